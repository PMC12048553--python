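"""Compound encoding: bit fingerprints, byte packing, Tanimoto similarity.

Compounds are encoded as a 4096-bit circular-substructure (Morgan) fingerprint
(radius 3, chirality-aware) concatenated with the 166 MACCS substructure keys,
giving 4262 bits. The bit string is packed losslessly, 8 bits per byte
(MSB-first), into 533 bytes; similarity is computed directly on the packed
bytes via popcounts, which reproduces the set-based Tanimoto

    T(a, b) = |a AND b| / (|a| + |b| - |a AND b|)

exactly — packing never changes the similarity value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FingerprintConfig",
    "CompoundRecord",
    "encode_fingerprint",
    "pack_bits",
    "unpack_bits",
    "tanimoto",
    "tanimoto_matrix",
    "tanimoto_cross",
    "popcount",
    "read_compound_table",
    "write_fingerprints",
    "read_fingerprints",
]

# number of set bits for each possible byte value
_POPCOUNT8 = np.array([bin(i).count("1") for i in range(256)], dtype=np.int64)


@dataclass(frozen=True)
class FingerprintConfig:
    """Parameters of the concatenated fingerprint.

    Defaults give the production 4262-bit layout (4096 Morgan + 166 MACCS).
    Synthetic fixtures use shorter toy lengths by disabling MACCS and
    shrinking ``morgan_bits``.
    """

    morgan_bits: int = 4096
    radius: int = 3
    use_chirality: bool = True
    include_maccs: bool = True

    @property
    def n_bits(self) -> int:
        return self.morgan_bits + (166 if self.include_maccs else 0)

    @property
    def n_bytes(self) -> int:
        return (self.n_bits + 7) // 8


@dataclass
class CompoundRecord:
    """One compound: identifier, optional SMILES, packed fingerprint and a
    dense learned-representation vector (length 300 by default)."""

    compound_id: str
    smiles: Optional[str]
    fingerprint: np.ndarray  # packed uint8, length config.n_bytes
    dense_repr: Optional[np.ndarray] = None
    n_bits: int = 4262


def encode_fingerprint(smiles: str, config: FingerprintConfig = FingerprintConfig(),
                       compound_id: str = "?") -> np.ndarray:
    """Encode a SMILES string as a {0,1} bit vector of length ``config.n_bits``.

    Raises ``ValueError`` naming ``compound_id`` when the SMILES does not
    parse. Deterministic: identical SMILES give identical bits.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator, MACCSkeys

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(
            f"unparsable SMILES for compound {compound_id!r}: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.radius,
        fpSize=config.morgan_bits,
        includeChirality=config.use_chirality,
    )
    morgan = np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8)
    if not config.include_maccs:
        return morgan
    maccs_fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 always unset
    maccs = np.zeros(166, dtype=np.uint8)
    for b in maccs_fp.GetOnBits():
        if b >= 1:
            maccs[b - 1] = 1
    return np.concatenate([morgan, maccs])


def pack_bits(bits: np.ndarray, n_bits: Optional[int] = None) -> np.ndarray:
    """Pack a {0,1} vector into bytes, MSB-first, zero-padded to 8 | length.

    A 4262-bit fingerprint packs into 533 bytes. Lossless: see
    :func:`unpack_bits`.
    """
    bits = np.asarray(bits)
    if n_bits is not None and bits.shape[-1] != n_bits:
        raise ValueError(
            f"expected {n_bits} bits, got {bits.shape[-1]}")
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("fingerprint bits must be 0 or 1")
    return np.packbits(bits.astype(np.uint8), axis=-1)


def unpack_bits(packed: np.ndarray, n_bits: int) -> np.ndarray:
    """Inverse of :func:`pack_bits` on the first ``n_bits`` positions."""
    return np.unpackbits(np.asarray(packed, dtype=np.uint8), axis=-1)[..., :n_bits]


def popcount(packed: np.ndarray) -> np.ndarray:
    """Number of set bits per packed fingerprint (last axis summed)."""
    return _POPCOUNT8[np.asarray(packed, dtype=np.uint8)].sum(axis=-1)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity of two packed fingerprints.

    ``|a AND b| / (|a| + |b| - |a AND b|)``, exactly the set formula on the
    unpacked bits. Two all-zero fingerprints have similarity 0 by convention
    (an empty bit set should match nothing).
    """
    a = np.asarray(a, dtype=np.uint8)
    b = np.asarray(b, dtype=np.uint8)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    inter = int(popcount(a & b))
    union = int(popcount(a)) + int(popcount(b)) - inter
    if union == 0:
        return 0.0
    return inter / union


def tanimoto_matrix(packed: np.ndarray) -> np.ndarray:
    """All-vs-all Tanimoto similarity for an (n, n_bytes) packed array.

    Unpacks to {0,1} and uses an integer Gram matrix; exact (integer counts,
    one final division). Diagonal is 1 for non-empty fingerprints, 0 for
    all-zero rows.
    """
    packed = np.asarray(packed, dtype=np.uint8)
    bits = np.unpackbits(packed, axis=1).astype(np.int64)
    inter = bits @ bits.T
    pop = bits.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return sim


def tanimoto_cross(packed_a: np.ndarray, packed_b: np.ndarray) -> np.ndarray:
    """Tanimoto similarity between two packed sets, shape (n_a, n_b)."""
    a = np.unpackbits(np.asarray(packed_a, dtype=np.uint8), axis=1).astype(np.int64)
    b = np.unpackbits(np.asarray(packed_b, dtype=np.uint8), axis=1).astype(np.int64)
    inter = a @ b.T
    union = a.sum(1)[:, None] + b.sum(1)[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(union > 0, inter / np.maximum(union, 1), 0.0)


def read_compound_table(path, config: FingerprintConfig = FingerprintConfig(),
                        sep: Optional[str] = None) -> list[CompoundRecord]:
    """Read a (compound_id, smiles) CSV/TSV and encode each compound."""
    df = pd.read_csv(path, sep=sep, engine="python")
    required = {"compound_id", "smiles"}
    if not required.issubset(df.columns):
        raise ValueError(f"compound table needs columns {sorted(required)}")
    ids = df["compound_id"].astype(str)
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate compound ids: {sorted(dup)}")
    records = []
    for cid, smi in zip(ids, df["smiles"].astype(str)):
        bits = encode_fingerprint(smi, config, compound_id=cid)
        records.append(CompoundRecord(
            compound_id=cid, smiles=smi,
            fingerprint=pack_bits(bits, config.n_bits),
            n_bits=config.n_bits))
    return records


_FP_FORMAT_VERSION = 1


def write_fingerprints(records: Sequence[CompoundRecord], out_dir) -> None:
    """Write packed fingerprints (.npy) plus a CSV id index and JSON sidecar."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = np.stack([r.fingerprint for r in records])
    np.save(out / "fingerprints.npy", mat)
    pd.DataFrame({"row": range(len(records)),
                  "compound_id": [r.compound_id for r in records]}
                 ).to_csv(out / "index.csv", index=False)
    (out / "meta.json").write_text(json.dumps(
        {"format_version": _FP_FORMAT_VERSION,
         "n_bits": records[0].n_bits,
         "n_bytes": int(mat.shape[1])}))


def read_fingerprints(in_dir) -> list[CompoundRecord]:
    import json
    from pathlib import Path

    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    mat = np.load(src / "fingerprints.npy")
    idx = pd.read_csv(src / "index.csv")
    return [CompoundRecord(compound_id=str(cid), smiles=None,
                           fingerprint=mat[row], n_bits=meta["n_bits"])
            for row, cid in zip(idx["row"], idx["compound_id"])]
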