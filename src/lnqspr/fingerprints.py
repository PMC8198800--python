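"""Feature-class circular fingerprints with bit-to-fragment provenance.

Circular (Morgan) fingerprints hash every atom neighbourhood up to a
bond radius into 32-bit identifiers which are folded, by modulus, into
a fixed-length bit vector.  Folding makes bits ambiguous: two distinct
atom environments can land on the same bit (a *collision*), and a bit
is only chemically interpretable when every environment observed at it
in the dataset is the same fragment.  This module therefore keeps, for
every bit, the full map back to the atom environments that set it, so
collisions are detectable and any clean bit can be depicted as a
substructure.

Atom invariants are either pharmacophoric feature classes (donor,
acceptor, aromatic, halogen, basic, acidic - the FCFP convention,
default here) or connectivity-based ECFP invariants.  Hashing is
RDKit's Morgan invariant-update hash, which is stable across runs and
pinned by the RDKit release; folding to ``n_bits`` is a plain modulus
applied in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .exceptions import InvalidSmilesError, LnqsprError


@dataclass(frozen=True)
class FingerprintSpec:
    """Parameters of the circular fingerprint.

    radius is in bonds; 2 keeps fragments small enough to read as
    functional groups.  256 bits trades collision rate against model
    input width.  ``counted`` keeps per-molecule environment counts
    instead of binary presence.
    """

    radius: int = 2
    n_bits: int = 256
    invariant_set: str = "chemical_feature"  # or "connectivity"
    counted: bool = False

    def __post_init__(self) -> None:
        if self.n_bits < 16:
            raise ValueError("n_bits must be >= 16")
        if not 0 <= self.radius <= 6:
            raise ValueError("radius must lie in [0, 6]")
        if self.invariant_set not in ("chemical_feature", "connectivity"):
            raise ValueError("invariant_set must be chemical_feature or connectivity")


@dataclass(frozen=True)
class BitEnvironment:
    """One observed atom neighbourhood contributing to a bit."""

    molecule_index: int
    center_atom_index: int
    radius_used: int
    environment_key: str


@dataclass
class FingerprintMatrix:
    """Folded fingerprint matrix plus full bit provenance.

    ``provenance[bit]`` maps each distinct environment key observed at
    that bit to the list of :class:`BitEnvironment` occurrences; a bit
    with more than one key is a collision.
    """

    X: np.ndarray
    provenance: dict[int, dict[str, list[BitEnvironment]]]
    spec: FingerprintSpec
    smiles: list[str] = field(default_factory=list)

    @property
    def n_molecules(self) -> int:
        return self.X.shape[0]


def _environment_key(mol: Chem.Mol, center: int, radius: int) -> str:
    """Canonical SMILES of the radius-r neighbourhood, center mapped as :1."""
    marked = Chem.RWMol(mol)
    for atom in marked.GetAtoms():
        atom.SetAtomMapNum(0)
    marked.GetAtomWithIdx(center).SetAtomMapNum(1)
    if radius == 0:
        return Chem.MolFragmentToSmiles(marked, atomsToUse=[center], canonical=True)
    bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, center)
    atoms = {center}
    for b in bonds:
        bond = mol.GetBondWithIdx(b)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return Chem.MolFragmentToSmiles(
        marked, atomsToUse=sorted(atoms), bondsToUse=list(bonds), canonical=True
    )


def _make_generator(spec: FingerprintSpec):
    if spec.invariant_set == "chemical_feature":
        inv = rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
        return rdFingerprintGenerator.GetMorganGenerator(
            radius=spec.radius, atomInvariantsGenerator=inv
        )
    return rdFingerprintGenerator.GetMorganGenerator(radius=spec.radius)


def fingerprint_dataset(
    smiles: Sequence[str], spec: FingerprintSpec | None = None
) -> FingerprintMatrix:
    """Fingerprint a standardized SMILES list with full provenance.

    Deterministic for fixed input and spec.  Raises
    :class:`InvalidSmilesError` naming the offending index when a
    SMILES does not parse.
    """
    spec = spec or FingerprintSpec()
    gen = _make_generator(spec)
    n = len(smiles)
    X = np.zeros((n, spec.n_bits), dtype=np.int64 if spec.counted else np.uint8)
    provenance: dict[int, dict[str, list[BitEnvironment]]] = {}
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise InvalidSmilesError(f"molecule {i}: cannot parse SMILES {smi!r}")
        ao = rdFingerprintGenerator.AdditionalOutput()
        ao.AllocateBitInfoMap()
        gen.GetSparseCountFingerprint(mol, additionalOutput=ao)
        for raw_id, hits in ao.GetBitInfoMap().items():
            bit = int(raw_id % spec.n_bits)
            for center, radius in hits:
                key = _environment_key(mol, center, radius)
                env = BitEnvironment(i, center, radius, key)
                provenance.setdefault(bit, {}).setdefault(key, []).append(env)
                if spec.counted:
                    X[i, bit] += 1
                else:
                    X[i, bit] = 1
    return FingerprintMatrix(X=X, provenance=provenance, spec=spec, smiles=list(smiles))


def detect_collisions(fp: FingerprintMatrix) -> set[int]:
    """Bits at which two or more distinct environments were observed.

    Collision status is relative to the dataset the matrix was built
    from: only environments actually observed count.
    """
    return {
        bit for bit, envs in fp.provenance.items() if len(envs) >= 2
    }


def depict_bit(fp: FingerprintMatrix, bit: int) -> list[str]:
    """Distinct environment keys behind an active bit.

    Non-colliding bits give a single substructure SMILES (the fragment
    the bit means); colliding bits list every observed alternative.
    """
    if bit not in fp.provenance:
        raise LnqsprError(f"bit {bit} is not active in this dataset")
    return sorted(fp.provenance[bit])


def collision_profile(
    smiles: Sequence[str],
    n_bits_grid: Iterable[int] = (64, 128, 256, 512),
    radius: int = 2,
    invariant_set: str = "chemical_feature",
) -> dict[int, int]:
    """Colliding-bit count as a function of fingerprint length."""
    out = {}
    for n_bits in n_bits_grid:
        fp = fingerprint_dataset(
            smiles,
            FingerprintSpec(radius=radius, n_bits=n_bits, invariant_set=invariant_set),
        )
        out[n_bits] = len(detect_collisions(fp))
    return out
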