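"""Core domain types shared by every module.

These containers are deliberately free of I/O and of any chemistry-toolkit
dependency: a :class:`BitMatrix` is just molecules x bits, however the bits
were produced (MACCS keys, folded ECFP4, or a synthetic generator), and a
:class:`BitCountProfile` is its per-bit "1"-count summary.  All cross-object
operations require matching ``scheme_tag`` values — comparing MACCS bits to
ECFP4 bits is meaningless, so a mismatch is always an error, never a silent
recycle.  Bit indices are 0-based everywhere in memory; serialized profiles
carry an explicit bit-index column so 1-based external sources can be
ingested with an offset flag (see :mod:`sbdfp.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BitMatrix",
    "BitCountProfile",
    "ZTestResult",
    "DatabaseFingerprint",
    "SimilarityMatrix",
    "SchemeMismatchError",
]

#: methodology tags for condensed-fingerprint construction
METHOD_DFP = "DFP"
METHOD_SBDFP = "SB-DFP"
METHODOLOGY_ACC = "ACC"

_VALID_METHODS = (METHOD_DFP, METHOD_SBDFP)
_VALID_MATRIX_METHODOLOGIES = (METHODOLOGY_ACC, METHOD_DFP, METHOD_SBDFP)


class SchemeMismatchError(ValueError):
    """Raised when two objects with different fingerprint schemes are combined."""


def check_same_scheme(a, b) -> None:
    """Require matching ``scheme_tag`` (and ``n_bits`` where present)."""
    if a.scheme_tag != b.scheme_tag:
        raise SchemeMismatchError(
            f"fingerprint scheme mismatch: {a.scheme_tag!r} vs {b.scheme_tag!r}"
        )
    if getattr(a, "n_bits", None) != getattr(b, "n_bits", None):
        raise SchemeMismatchError(
            f"bit-length mismatch: {a.n_bits} vs {b.n_bits}"
        )


def _as_binary(arr, name: str) -> np.ndarray:
    out = np.asarray(arr, dtype=np.uint8)
    check = np.asarray(arr)
    if check.size and not np.isin(check, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return out


@dataclass
class BitMatrix:
    """Binary fingerprint matrix: one row per molecule, one column per bit.

    Parameters
    ----------
    ids:
        Unique molecule identifiers, aligned with ``rows``.
    rows:
        ``n_molecules x n_bits`` array of {0, 1}.
    scheme_tag:
        Label of the fingerprint scheme, e.g. ``"MACCS-166"``,
        ``"ECFP4-2048"`` or ``"synthetic"``.
    """

    ids: list[str]
    rows: np.ndarray
    scheme_tag: str

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.rows = np.atleast_2d(_as_binary(self.rows, "rows"))
        if len(self.ids) != self.rows.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids for {self.rows.shape[0]} fingerprint rows"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("molecule identifiers must be unique within a matrix")
        if self.rows.shape[1] < 1:
            raise ValueError("fingerprints must have at least one bit")

    @property
    def n_bits(self) -> int:
        return int(self.rows.shape[1])

    @property
    def n_molecules(self) -> int:
        return int(self.rows.shape[0])

    def subset(self, indices: Sequence[int]) -> "BitMatrix":
        """New matrix restricted to the given row indices (order preserved)."""
        idx = list(indices)
        return BitMatrix(
            ids=[self.ids[i] for i in idx],
            rows=self.rows[idx],
            scheme_tag=self.scheme_tag,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, BitMatrix):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.scheme_tag == other.scheme_tag
            and self.rows.shape == other.rows.shape
            and bool((self.rows == other.rows).all())
        )


@dataclass
class BitCountProfile:
    """Per-bit "1"-counts over ``n_obs`` molecules.

    Holds the (count, n) pair on either side of the two-proportion test:
    built on the reference collection it carries (p_r, n_r); built on a
    target set it carries (p_t, n_t).
    """

    counts: np.ndarray
    n_obs: int
    scheme_tag: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.n_obs = int(self.n_obs)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if self.n_obs < 1:
            raise ValueError("profile must summarize at least one molecule")
        if (self.counts < 0).any() or (self.counts > self.n_obs).any():
            raise ValueError("bit counts must lie in [0, n_obs]")

    @property
    def n_bits(self) -> int:
        return int(self.counts.shape[0])

    @property
    def proportions(self) -> np.ndarray:
        """Per-bit "1"-frequency, counts / n_obs."""
        return self.counts / float(self.n_obs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BitCountProfile):
            return NotImplemented
        return (
            self.n_obs == other.n_obs
            and self.scheme_tag == other.scheme_tag
            and self.counts.shape == other.counts.shape
            and bool((self.counts == other.counts).all())
        )


@dataclass(frozen=True)
class ZTestResult:
    """Outcome of the one-sided two-proportion Z-test for a single bit.

    ``p_one_sided`` is the probability that an excess at least as large as the
    observed one arises by chance under equal proportions, i.e.
    ``1 - Phi(z)``; in the degenerate pooled cases (pooled proportion 0 or 1)
    it is defined as 0.5 with ``z = 0``.
    """

    z: float
    p_one_sided: float
    pooled_p: float
    p_t: float
    p_r: float


@dataclass
class DatabaseFingerprint:
    """A compound set condensed into a single binary fingerprint.

    ``method`` is ``"DFP"`` (threshold rule: bit set iff present in at least
    ``param`` of the molecules, default 0.5) or ``"SB-DFP"`` (statistical
    rule: bit set iff its frequency is significantly higher than in the
    reference collection at level ``param``, default alpha = 0.01).
    """

    bits: np.ndarray
    method: str
    param: float
    n_source: int
    scheme_tag: str

    def __post_init__(self) -> None:
        self.bits = np.ravel(_as_binary(self.bits, "bits"))
        if self.method not in _VALID_METHODS:
            raise ValueError(f"method must be one of {_VALID_METHODS}, got {self.method!r}")
        self.param = float(self.param)
        self.n_source = int(self.n_source)
        if self.n_source < 1:
            raise ValueError("a database fingerprint must condense at least one molecule")

    @property
    def n_bits(self) -> int:
        return int(self.bits.shape[0])

    @property
    def n_on_bits(self) -> int:
        """Number of set bits — the paper-style 'amount of information' count."""
        return int(self.bits.sum())

    def __eq__(self, other) -> bool:
        if not isinstance(other, DatabaseFingerprint):
            return NotImplemented
        return (
            self.method == other.method
            and self.param == other.param
            and self.n_source == other.n_source
            and self.scheme_tag == other.scheme_tag
            and self.bits.shape == other.bits.shape
            and bool((self.bits == other.bits).all())
        )


@dataclass
class SimilarityMatrix:
    """Square inter-dataset similarity matrix for one methodology.

    For ``DFP``/``SB-DFP`` methodologies the diagonal is exactly 1 (a set is
    maximally similar to itself under a single-fingerprint comparison); for
    ``ACC`` the diagonal is the intra-set median Tanimoto and need not be 1.
    """

    labels: list[str]
    values: np.ndarray
    methodology: str
    scheme_tag: str

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"values must be {n}x{n} to match labels")
        if self.methodology not in _VALID_MATRIX_METHODOLOGIES:
            raise ValueError(
                f"methodology must be one of {_VALID_MATRIX_METHODOLOGIES}, "
                f"got {self.methodology!r}"
            )
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("similarity values must lie in [0, 1]")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")
        if self.methodology in _VALID_METHODS and not np.all(np.diag(self.values) == 1.0):
            raise ValueError(f"{self.methodology} similarity matrix must have unit diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SimilarityMatrix):
            return NotImplemented
        return (
            self.labels == other.labels
            and self.methodology == other.methodology
            and self.scheme_tag == other.scheme_tag
            and self.values.shape == other.values.shape
            and bool(np.allclose(self.values, other.values))
        )
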