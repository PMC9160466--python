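"""Core data containers: Likert and binary response matrices and Ising networks.

Containers are thin, validated wrappers around :class:`numpy.ndarray` with
item-code bookkeeping.  Tabular I/O goes through :mod:`pandas`; networks
serialize to JSON and 3-column edge lists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    InvalidNetworkError,
    InvalidResponseError,
    MissingItemError,
)

__all__ = [
    "LikertMatrix",
    "BinaryMatrix",
    "IsingNetwork",
]


def _check_codes(item_codes: Sequence[str]) -> list[str]:
    codes = [str(c) for c in item_codes]
    if len(set(codes)) != len(codes):
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        raise InvalidNetworkError(f"duplicate item codes: {dupes}")
    return codes


@dataclass
class LikertMatrix:
    """Subjects x items matrix of 5-point Likert responses (integers 1-5).

    Parameters
    ----------
    values
        Integer array of shape ``(n_subjects, n_items)`` with entries in
        ``{1, 2, 3, 4, 5}``.
    item_codes
        Column labels (short symptom codes), unique.
    group
        Optional per-subject group label (e.g. two study samples), used by
        the two-sample comparison machinery.
    """

    values: np.ndarray
    item_codes: list[str]
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.item_codes = _check_codes(self.item_codes)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.item_codes):
            raise InvalidResponseError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.item_codes)} item codes"
            )
        if not np.issubdtype(self.values.dtype, np.integer):
            as_int = self.values.astype(int)
            if not np.array_equal(as_int, self.values):
                raise InvalidResponseError("Likert responses must be integers")
            self.values = as_int
        bad = (self.values < 1) | (self.values > 5)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise InvalidResponseError(
                f"response {self.values[r, c]} at subject {r}, "
                f"item {self.item_codes[c]!r} outside 1-5"
            )
        if self.group is not None:
            self.group = np.asarray(self.group)
            if self.group.shape[0] != self.values.shape[0]:
                raise InvalidResponseError("group labels must match subject count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.item_codes)
        if self.group is not None:
            df.insert(0, "group", self.group)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group_column: str | None = None) -> "LikertMatrix":
        group = None
        if group_column is not None and group_column in df.columns:
            group = df[group_column].to_numpy()
            df = df.drop(columns=[group_column])
        return cls(df.to_numpy(), list(df.columns), group=group)

    @classmethod
    def from_csv(cls, path: str | Path, group_column: str | None = "group") -> "LikertMatrix":
        df = pd.read_csv(path)
        if group_column is not None and group_column not in df.columns:
            group_column = None
        return cls.from_frame(df, group_column=group_column)

    def subset(self, mask: np.ndarray) -> "LikertMatrix":
        group = self.group[mask] if self.group is not None else None
        return LikertMatrix(self.values[mask], list(self.item_codes), group=group)


@dataclass
class BinaryMatrix:
    """Subjects x items matrix of 0/1 symptom indicators."""

    values: np.ndarray
    item_codes: list[str]
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.item_codes = _check_codes(self.item_codes)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.item_codes):
            raise InvalidResponseError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.item_codes)} item codes"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise InvalidResponseError("binary matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        if self.group is not None:
            self.group = np.asarray(self.group)
            if self.group.shape[0] != self.values.shape[0]:
                raise InvalidResponseError("group labels must match subject count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.item_codes)
        if self.group is not None:
            df.insert(0, "group", self.group)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, group_column: str | None = "group") -> "BinaryMatrix":
        df = pd.read_csv(path)
        group = None
        if group_column is not None and group_column in df.columns:
            group = df[group_column].to_numpy()
            df = df.drop(columns=[group_column])
        return cls(df.to_numpy(), list(df.columns), group=group)

    def subset(self, mask: np.ndarray) -> "BinaryMatrix":
        group = self.group[mask] if self.group is not None else None
        return BinaryMatrix(self.values[mask], list(self.item_codes), group=group)


@dataclass
class IsingNetwork:
    """Pairwise binary Markov random field over symptom indicators.

    The model assigns each binary state vector ``x`` (coded 0/1) probability
    proportional to ``exp(sum_i tau_i x_i + sum_{i<j} w_ij x_i x_j)`` where
    ``tau`` are the node thresholds (intercepts) and ``w`` the symmetric
    edge-weight matrix with zero diagonal.
    """

    item_codes: list[str]
    weights: np.ndarray
    thresholds: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.item_codes = _check_codes(self.item_codes)
        self.weights = np.asarray(self.weights, dtype=float)
        p = len(self.item_codes)
        if self.weights.shape != (p, p):
            raise InvalidNetworkError(
                f"weights shape {self.weights.shape} does not match {p} items"
            )
        if not np.allclose(self.weights, self.weights.T, atol=1e-10):
            raise InvalidNetworkError("weights matrix must be symmetric")
        if not np.allclose(np.diag(self.weights), 0.0):
            raise InvalidNetworkError("weights diagonal must be exactly zero")
        np.fill_diagonal(self.weights, 0.0)
        self.weights = (self.weights + self.weights.T) / 2.0
        if self.thresholds is None:
            self.thresholds = np.zeros(p)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.shape != (p,):
            raise InvalidNetworkError(
                f"thresholds shape {self.thresholds.shape} does not match {p} items"
            )

    @property
    def n_items(self) -> int:
        return len(self.item_codes)

    @property
    def density(self) -> float:
        """Fraction of item pairs with a nonzero edge."""
        p = self.n_items
        if p < 2:
            return 0.0
        iu = np.triu_indices(p, k=1)
        return float(np.count_nonzero(self.weights[iu]) / len(iu[0]))

    def index(self, code: str) -> int:
        try:
            return self.item_codes.index(code)
        except ValueError:
            raise MissingItemError(
                f"item {code!r} not in network (items: {self.item_codes})"
            ) from None

    def edge(self, code_a: str, code_b: str) -> float:
        return float(self.weights[self.index(code_a), self.index(code_b)])

    def to_dict(self) -> dict:
        return {
            "item_codes": list(self.item_codes),
            "weights": self.weights.tolist(),
            "thresholds": self.thresholds.tolist(),
            "density": self.density,
        }

    def to_json(self, path: str | Path, **extra) -> None:
        payload = self.to_dict()
        payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "IsingNetwork":
        payload = json.loads(Path(path).read_text())
        return cls(
            payload["item_codes"],
            np.asarray(payload["weights"], dtype=float),
            np.asarray(payload["thresholds"], dtype=float),
        )

    def edge_list(self, nonzero_only: bool = True) -> pd.DataFrame:
        """Upper-triangle edges as a 3-column table (item_a, item_b, weight)."""
        rows = []
        p = self.n_items
        for i in range(p):
            for j in range(i + 1, p):
                w = self.weights[i, j]
                if nonzero_only and w == 0.0:
                    continue
                rows.append((self.item_codes[i], self.item_codes[j], w))
        return pd.DataFrame(rows, columns=["item_a", "item_b", "weight"])
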