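"""Chemistry-toolkit adapter: SMILES records in, bit matrices out.

RDKit is an optional dependency, imported lazily: every analytical module
accepts precomputed fingerprint files, so the statistical core is fully
usable (and testable) with no chemistry stack installed.

Two schemes are supported.  ``MACCS-166`` is the 166-key dictionary
fingerprint; RDKit emits 167 positions with index 0 as an unused
placeholder, so keys 1..166 are re-based to bit indices 0..165 (key ``k``
is stored at index ``k - 1``).  ``ECFP4-2048`` is the extended-connectivity
circular fingerprint of diameter 4 (Morgan radius 2) hashed and folded to
2048 bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BitMatrix

__all__ = ["SCHEMES", "fingerprint_molecules", "RejectionReport"]

SCHEMES = ("MACCS-166", "ECFP4-2048")


@dataclass
class RejectionReport:
    """Molecules dropped during fingerprinting, with the reason."""

    rejected: list[tuple[str, str, str]]  # (identifier, smiles, reason)

    def __len__(self) -> int:
        return len(self.rejected)


def _require_rdkit():
    try:
        from rdkit import Chem, RDLogger
        from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - depends on install
        raise ImportError(
            "RDKit is required for SMILES fingerprinting; install the 'chem' "
            "extra or supply precomputed bit-matrix files instead"
        ) from exc
    RDLogger.DisableLog("rdApp.error")
    return Chem, MACCSkeys, rdFingerprintGenerator


def fingerprint_molecules(
    records: list[tuple[str, str]], scheme: str
) -> tuple[BitMatrix, RejectionReport]:
    """Fingerprint (identifier, SMILES) records under one scheme.

    Unparseable SMILES are dropped and listed in the rejection report,
    never silently; if nothing parses, that is an error.  Output is
    deterministic for a given input and toolkit version.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    Chem, MACCSkeys, rdFingerprintGenerator = _require_rdkit()

    morgan = None
    if scheme == "ECFP4-2048":
        morgan = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)

    ids: list[str] = []
    rows: list[np.ndarray] = []
    rejected: list[tuple[str, str, str]] = []
    for ident, smiles in records:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            rejected.append((ident, smiles, "SMILES could not be parsed"))
            continue
        if scheme == "MACCS-166":
            fp = MACCSkeys.GenMACCSKeys(mol)
            bits = np.zeros(167, dtype=np.uint8)
            bits[list(fp.GetOnBits())] = 1
            bits = bits[1:]  # drop placeholder key 0 -> 166 bits, 0-based
        else:
            fp = morgan.GetFingerprint(mol)
            bits = np.zeros(2048, dtype=np.uint8)
            bits[list(fp.GetOnBits())] = 1
        ids.append(ident)
        rows.append(bits)

    if not rows:
        raise ValueError("no molecule could be fingerprinted")
    matrix = BitMatrix(ids=ids, rows=np.vstack(rows), scheme_tag=scheme)
    return matrix, RejectionReport(rejected=rejected)
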