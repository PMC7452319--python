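"""Experimental design helpers: mixture ratio series and serial dilutions.

The reference design mixes the two agents at 9:1, 4:1, 1:1, 1:4 and 1:9
(parts by weight) and doses each mixture over a 5-level 10-fold serial
dilution of the stock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cotoxicity import MixtureRatio
from .exceptions import InputDataError

__all__ = ["DilutionSeries", "DEFAULT_RATIO_PARTS", "build_ratio_series", "serial_dilution"]

DEFAULT_RATIO_PARTS: tuple[tuple[int, int], ...] = ((9, 1), (4, 1), (1, 1), (1, 4), (1, 9))


@dataclass(frozen=True)
class DilutionSeries:
    """A geometric dose gradient: stock / fold^i for i = 0..levels-1."""

    stock_concentration: float
    unit: str
    fold: float
    levels: int
    concentrations: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.stock_concentration <= 0:
            raise InputDataError(f"stock concentration must be positive, got {self.stock_concentration}")
        if self.fold <= 1:
            raise InputDataError(f"dilution fold must exceed 1, got {self.fold}")
        if self.levels < 1:
            raise InputDataError(f"need at least 1 dilution level, got {self.levels}")
        conc = tuple(self.stock_concentration / self.fold**i for i in range(self.levels))
        object.__setattr__(self, "concentrations", conc)


def serial_dilution(stock: float, fold: float = 10.0, levels: int = 5, unit: str = "mg/L") -> DilutionSeries:
    """Serially dilute ``stock`` by ``fold`` into ``levels`` concentrations.

    ``serial_dilution(500, 10, 5)`` gives [500, 50, 5, 0.5, 0.05] — the
    1x, 10x, ..., 10000x gradient of the reference design.
    """
    return DilutionSeries(stock_concentration=stock, unit=unit, fold=fold, levels=levels)


def build_ratio_series(parts: list[tuple[float, float]] | None = None) -> list[MixtureRatio]:
    """Normalize a list of part pairs into :class:`MixtureRatio` objects.

    With no argument, returns the default five-ratio series
    9:1, 4:1, 1:1, 1:4, 1:9.
    """
    if parts is None:
        parts = list(DEFAULT_RATIO_PARTS)
    return [MixtureRatio.from_parts(a, b) for a, b in parts]
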