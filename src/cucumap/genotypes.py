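"""Genotype matrices for F2 and RIL mapping populations.

Calls are stored as small integers: 0 = AA ("A"), 1 = AB ("H"), 2 = BB ("B"),
-1 = missing ("-").  RIL matrices (selfed lines at fixation) contain no AB
calls.  The on-disk format is a tab-delimited table with a header row of
individual ids and one marker per row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

F2 = "F2"
RIL = "RIL"

CODE_TO_INT = {"A": 0, "H": 1, "B": 2, "-": -1}
INT_TO_CODE = {v: k for k, v in CODE_TO_INT.items()}

MISSING = -1


class GenotypeError(ValueError):
    """Raised on malformed genotype input."""


def encode_calls(calls) -> np.ndarray:
    """Convert letter codes (A/H/B/-) or integers to the int8 representation."""
    arr = np.asarray(calls)
    if arr.dtype.kind in "iu":
        out = arr.astype(np.int8)
    else:
        try:
            out = np.array([CODE_TO_INT[str(c)] for c in arr.ravel()], dtype=np.int8)
        except KeyError as exc:  # pragma: no cover - message matters, not path
            raise GenotypeError(f"unknown genotype code {exc.args[0]!r}") from exc
        out = out.reshape(arr.shape)
    if out.size and (out.max() > 2 or out.min() < -1):
        raise GenotypeError("genotype codes must be in {A,H,B,-} / {0,1,2,-1}")
    return out


@dataclass
class GenotypeMatrix:
    """Marker-by-individual call matrix for a single mapping population."""

    marker_ids: list[str]
    individuals: list[str]
    calls: np.ndarray  # int8, shape (n_markers, n_individuals)
    population_kind: str

    def __post_init__(self):
        self.calls = encode_calls(self.calls)
        if self.calls.shape != (len(self.marker_ids), len(self.individuals)):
            raise GenotypeError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.marker_ids)} markers x {len(self.individuals)} individuals"
            )
        if self.population_kind not in (F2, RIL):
            raise GenotypeError(f"population_kind must be F2 or RIL, got {self.population_kind!r}")
        if self.population_kind == RIL and (self.calls == 1).any():
            raise GenotypeError("RIL matrix contains heterozygous (AB) calls")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise GenotypeError("duplicate marker ids")
        self._index = {m: i for i, m in enumerate(self.marker_ids)}

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def row(self, marker_id: str) -> np.ndarray:
        return self.calls[self._index[marker_id]]

    def missing_counts(self) -> dict[str, int]:
        miss = (self.calls == MISSING).sum(axis=1)
        return dict(zip(self.marker_ids, (int(m) for m in miss)))

    def subset(self, marker_ids) -> "GenotypeMatrix":
        idx = [self._index[m] for m in marker_ids]
        return GenotypeMatrix(
            list(marker_ids), list(self.individuals), self.calls[idx].copy(), self.population_kind
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.marker_ids), list(self.individuals), self.calls.copy(), self.population_kind
        )

    def to_frame(self) -> pd.DataFrame:
        letters = np.vectorize(INT_TO_CODE.get)(self.calls)
        return pd.DataFrame(letters, index=self.marker_ids, columns=self.individuals)

    def write(self, path) -> None:
        df = self.to_frame()
        df.index.name = "marker"
        df.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path, population_kind: str) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return cls(
            [str(m) for m in df.index],
            [str(c) for c in df.columns],
            encode_calls(df.to_numpy()),
            population_kind,
        )


def ril_heterozygotes_to_missing(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Return a RIL-valid copy with any AB calls recoded as missing (warns)."""
    calls = matrix.calls.copy()
    n_het = int((calls == 1).sum())
    if n_het:
        warnings.warn(
            f"{n_het} heterozygous calls in RIL data treated as missing", stacklevel=2
        )
        calls[calls == 1] = MISSING
    return GenotypeMatrix(list(matrix.marker_ids), list(matrix.individuals), calls, RIL)
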