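"""Plain-text I/O for compound lists, bit matrices, profiles and matrices.

All tabular formats are TSV with ``#key=value`` header lines carrying the
scheme tag, bit count and (for profiles) the observation count, so files
are self-describing and every writer/reader pair round-trips losslessly.
Bit-matrix rows can be stored as raw 0/1 strings (``bitstring`` dialect,
diffable) or hex (``hex`` dialect, compact); both decode identically.
Profiles carry an explicit bit-index column, so 1-based external sources
can be ingested with ``index_base=1``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BitCountProfile, BitMatrix, DatabaseFingerprint, SimilarityMatrix

__all__ = [
    "read_smiles",
    "write_bitmatrix",
    "read_bitmatrix",
    "write_profile",
    "read_profile",
    "write_dbfp",
    "read_dbfp",
    "write_similarity_matrix",
    "read_square_matrix",
]

logger = logging.getLogger(__name__)


def read_smiles(path) -> list[tuple[str, str]]:
    """Parse a SMILES file: one molecule per line, ``SMILES [identifier]``.

    Records missing an identifier get ``mol_<line-index>`` (0-based).
    Blank lines and ``#`` comments are skipped; the skip count is logged.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    skipped = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                skipped += 1
                continue
            parts = line.split()
            smiles = parts[0]
            ident = parts[1] if len(parts) > 1 else f"mol_{lineno}"
            records.append((ident, smiles))
    if skipped:
        logger.info("read_smiles(%s): skipped %d blank/comment lines", path, skipped)
    if not records:
        raise ValueError(f"no valid SMILES records in {path}")
    return records


def _write_header(fh, **fields) -> None:
    for key, value in fields.items():
        fh.write(f"#{key}={value}\n")


def _read_header(path) -> tuple[dict[str, str], list[str]]:
    header: dict[str, str] = {}
    body: list[str] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#") and "=" in line:
                key, _, value = line[1:].partition("=")
                header[key.strip()] = value.strip()
            elif line.strip():
                body.append(line)
    return header, body


def _bits_to_hex(bits: np.ndarray) -> str:
    return np.packbits(bits).tobytes().hex()

def _hex_to_bits(hexstr: str, n_bits: int) -> np.ndarray:
    raw = np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8)
    return np.unpackbits(raw)[:n_bits]


def write_bitmatrix(path, matrix: BitMatrix, dialect: str = "bitstring") -> None:
    """Write a bit matrix as TSV: header lines, then ``id<TAB>row``."""
    if dialect not in ("bitstring", "hex"):
        raise ValueError("dialect must be 'bitstring' or 'hex'")
    with Path(path).open("w") as fh:
        _write_header(
            fh, scheme_tag=matrix.scheme_tag, n_bits=matrix.n_bits, dialect=dialect
        )
        for ident, row in zip(matrix.ids, matrix.rows):
            enc = (
                "".join(map(str, row.tolist()))
                if dialect == "bitstring"
                else _bits_to_hex(row)
            )
            fh.write(f"{ident}\t{enc}\n")


def read_bitmatrix(path) -> BitMatrix:
    header, body = _read_header(path)
    try:
        n_bits = int(header["n_bits"])
        scheme = header["scheme_tag"]
        dialect = header.get("dialect", "bitstring")
    except KeyError as exc:
        raise ValueError(f"{path}: missing header field {exc}") from exc
    ids, rows = [], []
    for i, line in enumerate(body, start=1):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: malformed row at data line {i}")
        ident, enc = parts
        if dialect == "hex":
            bits = _hex_to_bits(enc, n_bits)
        else:
            if len(enc) != n_bits or set(enc) - {"0", "1"}:
                raise ValueError(f"{path}: bad bitstring at data line {i}")
            bits = np.frombuffer(enc.encode(), dtype=np.uint8) - ord("0")
        if bits.shape[0] != n_bits:
            raise ValueError(f"{path}: wrong bit count at data line {i}")
        ids.append(ident)
        rows.append(bits)
    if not rows:
        raise ValueError(f"{path}: no fingerprint rows")
    return BitMatrix(ids=ids, rows=np.vstack(rows), scheme_tag=scheme)


def write_profile(path, profile: BitCountProfile) -> None:
    """Write a bit-frequency profile: header, then ``bit_index<TAB>count``."""
    with Path(path).open("w") as fh:
        _write_header(
            fh,
            scheme_tag=profile.scheme_tag,
            n_bits=profile.n_bits,
            n_obs=profile.n_obs,
        )
        fh.write("bit_index\tcount\n")
        for j, c in enumerate(profile.counts.tolist()):
            fh.write(f"{j}\t{c}\n")


def read_profile(path, index_base: int = 0) -> BitCountProfile:
    """Read a profile TSV; ``index_base=1`` ingests 1-based external tables."""
    header, body = _read_header(path)
    try:
        n_bits = int(header["n_bits"])
        n_obs = int(header["n_obs"])
        scheme = header["scheme_tag"]
    except KeyError as exc:
        raise ValueError(f"{path}: missing header field {exc}") from exc
    counts = np.zeros(n_bits, dtype=np.int64)
    seen = np.zeros(n_bits, dtype=bool)
    for i, line in enumerate(body, start=1):
        if line.startswith("bit_index"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: malformed row at data line {i}")
        try:
            j = int(parts[0]) - index_base
            c = int(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}: non-integer entry at data line {i}") from exc
        if not 0 <= j < n_bits:
            raise ValueError(f"{path}: bit index out of range at data line {i}")
        if not 0 <= c <= n_obs:
            raise ValueError(f"{path}: count outside [0, n_obs] at data line {i}")
        counts[j] = c
        seen[j] = True
    if not seen.all():
        missing = int((~seen).sum())
        raise ValueError(f"{path}: {missing} bit indices missing from profile")
    return BitCountProfile(counts=counts, n_obs=n_obs, scheme_tag=scheme)


def write_dbfp(path, fp: DatabaseFingerprint) -> None:
    """Write a condensed fingerprint: header (method, param, n_source) + bits."""
    with Path(path).open("w") as fh:
        _write_header(
            fh,
            scheme_tag=fp.scheme_tag,
            n_bits=fp.n_bits,
            method=fp.method,
            param=repr(fp.param),
            n_source=fp.n_source,
        )
        fh.write(f"{fp.method}\t{''.join(map(str, fp.bits.tolist()))}\n")


def read_dbfp(path) -> DatabaseFingerprint:
    header, body = _read_header(path)
    try:
        n_bits = int(header["n_bits"])
        bits_line = body[0].split("\t")[1]
    except (KeyError, IndexError) as exc:
        raise ValueError(f"{path}: malformed condensed-fingerprint file") from exc
    if len(bits_line) != n_bits:
        raise ValueError(f"{path}: bit count does not match header")
    return DatabaseFingerprint(
        bits=np.frombuffer(bits_line.encode(), dtype=np.uint8) - ord("0"),
        method=header["method"],
        param=float(header["param"]),
        n_source=int(header["n_source"]),
        scheme_tag=header["scheme_tag"],
    )


def write_similarity_matrix(
    path, sim: SimilarityMatrix, decimals: int | None = 3
) -> None:
    """Write a labelled square matrix as TSV (3 decimals by default;
    ``decimals=None`` keeps full precision)."""
    df = pd.DataFrame(sim.values, index=sim.labels, columns=sim.labels)
    if decimals is not None:
        df = df.round(decimals)
    with Path(path).open("w") as fh:
        _write_header(fh, methodology=sim.methodology, scheme_tag=sim.scheme_tag)
        df.to_csv(fh, sep="\t", index_label="dataset")


def read_square_matrix(path) -> pd.DataFrame:
    """Read a labelled square TSV matrix (similarity, distance or identity),
    ignoring ``#`` header lines."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1] or list(df.index) != list(df.columns):
        raise ValueError(f"{path}: expected a labelled square matrix")
    return df
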