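"""Pair-level twin data container.

A dataset is one row per twin pair: a zygosity label (``MZ``/``DZ``) and the
four phenotype values ``(x1, y1, x2, y2)``.  Internally values are a float
array; :class:`TwinDataset` round-trips losslessly through a pandas frame
with columns ``zygosity, x1, y1, x2, y2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PAIR_COLUMNS", "ZYGOSITIES", "TwinDataset", "as_twin_dataset"]

PAIR_COLUMNS = ("x1", "y1", "x2", "y2")
ZYGOSITIES = ("MZ", "DZ")


@dataclass(frozen=True)
class TwinDataset:
    values: np.ndarray  # (n, 4), ordered (x1, y1, x2, y2)
    zygosity: np.ndarray  # (n,) of "MZ"/"DZ"

    def __post_init__(self):
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if values.size == 0:
            values = values.reshape(0, 4)
        zyg = np.asarray(self.zygosity, dtype=object)
        if values.ndim != 2 or values.shape[1] != 4:
            raise ValueError("values must be an (n, 4) array (x1, y1, x2, y2)")
        if zyg.shape != (values.shape[0],):
            raise ValueError("zygosity must have one label per pair")
        bad = ~np.isin(zyg, ZYGOSITIES)
        if bad.any():
            raise ValueError(f"unknown zygosity code(s): {sorted(set(zyg[bad]))}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "zygosity", zyg)

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_mz(self) -> int:
        return int(np.sum(self.zygosity == "MZ"))

    @property
    def n_dz(self) -> int:
        return int(np.sum(self.zygosity == "DZ"))

    def n_datapoints(self) -> int:
        """Total observed (finite) data values — the FIML df numerator."""
        return int(np.isfinite(self.values).sum())

    def by_zygosity(self, zyg: str) -> np.ndarray:
        return self.values[self.zygosity == zyg]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(PAIR_COLUMNS))
        df.insert(0, "zygosity", self.zygosity)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TwinDataset":
        missing = [c for c in ("zygosity", *PAIR_COLUMNS) if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {missing}")
        return cls(
            values=df[list(PAIR_COLUMNS)].to_numpy(dtype=float),
            zygosity=df["zygosity"].to_numpy(dtype=object),
        )

    @classmethod
    def empty(cls) -> "TwinDataset":
        return cls(np.empty((0, 4)), np.empty((0,), dtype=object))

    @classmethod
    def concat(cls, parts) -> "TwinDataset":
        parts = list(parts)
        if not parts:
            return cls.empty()
        return cls(
            np.vstack([p.values for p in parts]),
            np.concatenate([p.zygosity for p in parts]),
        )


def as_twin_dataset(X, y=None) -> TwinDataset:
    """Coerce estimator input to a :class:`TwinDataset`.

    Accepts a TwinDataset, a DataFrame with a ``zygosity`` column, or an
    (n, 4) array together with a zygosity vector in ``y``.
    """
    if isinstance(X, TwinDataset):
        return X
    if isinstance(X, pd.DataFrame):
        return TwinDataset.from_frame(X)
    if y is None:
        raise ValueError(
            "array input needs zygosity labels: pass y with one 'MZ'/'DZ' per row"
        )
    return TwinDataset(values=np.asarray(X, dtype=float), zygosity=np.asarray(y, dtype=object))
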