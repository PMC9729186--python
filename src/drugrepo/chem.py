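"""ECFP4 fingerprints and Tanimoto structural similarity.

Fingerprints are Morgan circular fingerprints of radius 2 (the ECFP4
convention), folded to a fixed-length bit vector — 2048 bits by default,
the de-facto standard fold.  Each bit marks the presence or absence of a
circular substructure.  Similarity between an approved drug A and a
candidate compound C is the Tanimoto coefficient on set bits,

    TC = N_AC / (N_A + N_C - N_AC),

where N_A and N_C count set bits in each fingerprint and N_AC counts the
bits set in both.  TC lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .datamodel import CompoundRecord
from .errors import FingerprintLengthError, SmilesParseError

# RDKit writes parse diagnostics to its own C++ logger; failures are
# surfaced as SmilesParseError instead.
RDLogger.DisableLog("rdApp.error")

DEFAULT_N_BITS = 2048


@dataclass(eq=False)
class Fingerprint:
    """Fixed-length binary substructure vector."""

    bits: np.ndarray  # uint8 array of 0/1

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1:
            raise ValueError("fingerprint bits must be a 1-D vector")

    @property
    def n_bits(self) -> int:
        return int(self.bits.shape[0])

    @property
    def n_on(self) -> int:
        return int(np.count_nonzero(self.bits))

    def __eq__(self, other) -> bool:
        return isinstance(other, Fingerprint) and np.array_equal(self.bits, other.bits)

    def to_hex(self) -> str:
        """Hex encoding of the packed bit vector (for text caches)."""
        return np.packbits(self.bits).tobytes().hex()

    @classmethod
    def from_hex(cls, text: str, n_bits: int) -> "Fingerprint":
        unpacked = np.unpackbits(np.frombuffer(bytes.fromhex(text), dtype=np.uint8))
        return cls(bits=unpacked[:n_bits])


_generators: Dict[int, "rdFingerprintGenerator.FingerprintGenerator64"] = {}


def _generator(n_bits: int):
    if n_bits not in _generators:
        _generators[n_bits] = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    return _generators[n_bits]


def ecfp4_fingerprint(smiles: str, n_bits: int = DEFAULT_N_BITS) -> Fingerprint:
    """Compute the ECFP4 fingerprint of a SMILES string.

    The molecule is sanitized/canonicalized by RDKit first, so different
    writings of the same molecule (``CCO`` vs ``OCC``) give identical bits.

    Raises
    ------
    SmilesParseError
        If the SMILES does not parse to a valid molecule.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    bv = _generator(n_bits).GetFingerprint(mol)
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    return Fingerprint(bits=bits)


def tanimoto(fp_a: Fingerprint, fp_c: Fingerprint) -> float:
    """Tanimoto coefficient between two equal-length fingerprints.

    Both-empty fingerprints (the 0/0 case) return 0.0: a structureless
    match is never promoted.
    """
    if fp_a.n_bits != fp_c.n_bits:
        raise FingerprintLengthError(
            f"fingerprint lengths differ: {fp_a.n_bits} vs {fp_c.n_bits}"
        )
    n_ac = int(np.count_nonzero(fp_a.bits & fp_c.bits))
    denom = fp_a.n_on + fp_c.n_on - n_ac
    if denom == 0:
        return 0.0
    return n_ac / denom


def fingerprint_compounds(
    compounds: Iterable[CompoundRecord], n_bits: int = DEFAULT_N_BITS
) -> Tuple[Dict[str, Fingerprint], List[str]]:
    """Fingerprint a batch of compounds.

    Returns a mapping ``compound_id -> Fingerprint`` and the list of
    compound IDs whose SMILES failed to parse (excluded from scoring).
    """
    fps: Dict[str, Fingerprint] = {}
    failed: List[str] = []
    for rec in compounds:
        try:
            fps[rec.compound_id] = ecfp4_fingerprint(rec.smiles, n_bits=n_bits)
        except SmilesParseError:
            failed.append(rec.compound_id)
    return fps, failed
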