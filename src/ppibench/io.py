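"""Sequence, pair-table and embedding ingestion.

The data model mirrors a leakage-reduced PPI benchmark: protein
sequences (FASTA), tab-separated pair tables grouped into three
protein-disjoint splits (train / validation / test), and precomputed
language-model embeddings — a per-token matrix of shape
``(length, d_emb)`` per protein plus mean-pooled per-protein vectors —
held in an HDF5 container for random access.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "ProteinRecord",
    "PairTable",
    "SPLITS",
    "read_fasta",
    "write_fasta",
    "read_pair_table",
    "mean_pool",
    "length_filter",
    "pca_reduce",
    "EmbeddingStore",
]

SPLITS = ("train", "validation", "test")

# 20 standard residues; everything else recognisable is folded to X.
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_AA = set("BZJUOX*")


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


class FastaParseError(ValueError):
    pass


def _clean_sequence(raw: str, line_no: int) -> str:
    out = []
    for ch in raw.upper():
        if ch in STANDARD_AA:
            out.append(ch)
        elif ch in AMBIGUOUS_AA:
            out.append("X")  # alphabet only matters for alignment/length
        else:
            raise FastaParseError(
                f"illegal residue character {ch!r} on line {line_no}"
            )
    return "".join(out)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a FASTA file into :class:`ProteinRecord` objects.

    Multi-line bodies are concatenated; ids are the first whitespace
    token of the header.  Duplicate ids or malformed lines raise
    :class:`FastaParseError` naming the offending line.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    current_id: str | None = None
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal current_id, chunks
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(
                f"record {current_id!r} has an empty sequence (line {line_no})"
            )
        records.append(ProteinRecord(current_id, seq))
        current_id, chunks = None, []

    line_no = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"malformed header on line {line_no}")
                pid = header.split()[0]
                if pid in seen:
                    raise FastaParseError(
                        f"duplicate id {pid!r} on line {line_no}"
                    )
                seen.add(pid)
                current_id = pid
            else:
                if current_id is None:
                    raise FastaParseError(
                        f"sequence data before any header on line {line_no}"
                    )
                chunks.append(_clean_sequence(line, line_no))
        flush(line_no)
    return records


def write_fasta(path: str | Path, records: Iterable[ProteinRecord], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# pair tables
# ---------------------------------------------------------------------------
class PairTable:
    """Labeled protein-id pairs tagged with a split assignment.

    Wraps a DataFrame with columns ``idA, idB, label, split``; labels
    are 0 (non-interacting) / 1 (interacting), ids opaque strings.
    """

    COLUMNS = ("idA", "idB", "label", "split")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"pair table missing columns {sorted(missing)}")
        bad = set(df["label"].unique()) - {0, 1}
        if bad:
            raise ValueError(f"labels outside {{0,1}}: {sorted(bad)}")
        bad_split = set(df["split"].unique()) - set(SPLITS)
        if bad_split:
            raise ValueError(f"unknown split names {sorted(bad_split)}")
        self.df = df.reset_index(drop=True)[list(self.COLUMNS)]

    def __len__(self) -> int:
        return len(self.df)

    def split(self, name: str) -> pd.DataFrame:
        if name not in SPLITS:
            raise ValueError(f"unknown split {name!r}")
        return self.df[self.df["split"] == name].reset_index(drop=True)

    def protein_ids(self, split: str | None = None) -> set[str]:
        df = self.df if split is None else self.split(split)
        return set(df["idA"]) | set(df["idB"])

    def validate_disjoint(self) -> None:
        """Raise if any protein id occurs in two different splits."""
        sets = {s: self.protein_ids(s) for s in SPLITS}
        for i, a in enumerate(SPLITS):
            for b in SPLITS[i + 1 :]:
                overlap = sets[a] & sets[b]
                if overlap:
                    raise ValueError(
                        f"splits {a!r} and {b!r} share proteins, e.g. "
                        f"{sorted(overlap)[:5]}"
                    )

    def validate_balanced(self) -> None:
        """Raise unless every non-empty split has #pos == #neg."""
        for s in SPLITS:
            df = self.split(s)
            if len(df) == 0:
                continue
            n_pos = int((df["label"] == 1).sum())
            if 2 * n_pos != len(df):
                raise ValueError(
                    f"split {s!r} unbalanced: {n_pos} positives of {len(df)}"
                )

    @classmethod
    def concat(cls, tables: Sequence["PairTable"]) -> "PairTable":
        return cls(pd.concat([t.df for t in tables], ignore_index=True))


def read_pair_table(path: str | Path, split_name: str) -> PairTable:
    """Read a tab-separated ``idA<TAB>idB<TAB>label`` file into one split."""
    if split_name not in SPLITS:
        raise ValueError(f"unknown split {split_name!r}; use one of {SPLITS}")
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["idA", "idB", "label"],
            dtype={"idA": str, "idB": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["idA", "idB", "label"])
    labels = pd.to_numeric(df["label"], errors="raise")
    if not set(np.unique(labels.to_numpy())).issubset({0, 1}) and len(df):
        raise ValueError(f"labels outside {{0,1}} in {path}")
    df["label"] = labels.astype(int) if len(df) else labels
    df["split"] = split_name
    return PairTable(df)


def write_pair_table(path: str | Path, table: PairTable, split: str) -> None:
    table.split(split)[["idA", "idB", "label"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# pooling / filtering / PCA
# ---------------------------------------------------------------------------
def mean_pool(matrix: np.ndarray) -> np.ndarray:
    """Dimension-wise average of a per-token matrix -> per-protein vector."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] == 0:
        raise ValueError("mean_pool expects a non-empty (length, d_emb) matrix")
    return matrix.mean(axis=0)


def length_filter(
    pairs: PairTable,
    records: Mapping[str, ProteinRecord] | Iterable[ProteinRecord],
    max_len: int = 1000,
) -> PairTable:
    """Keep a pair iff both proteins have length <= ``max_len``.

    The cap is inclusive: a 1000-residue protein survives the default
    threshold.  Unresolvable ids raise, listing the offenders.
    """
    if not isinstance(records, Mapping):
        records = {r.id: r for r in records}
    ids_needed = pairs.protein_ids()
    missing = sorted(ids_needed - set(records))
    if missing:
        raise KeyError(f"pair table references unknown protein ids: {missing[:10]}")
    lengths = {pid: records[pid].length for pid in ids_needed}
    df = pairs.df
    keep = df.apply(
        lambda row: lengths[row["idA"]] <= max_len and lengths[row["idB"]] <= max_len,
        axis=1,
    ) if len(df) else pd.Series([], dtype=bool)
    return PairTable(df[keep] if len(df) else df)


def pca_reduce(
    vectors: np.ndarray, n_components: int
) -> tuple[np.ndarray, PCA]:
    """Project mean embeddings onto their first principal components.

    Fitted on everything it is given (matching a protocol that fits the
    PCA on the entire dataset of mean embeddings, train and test
    jointly); returns the reduced coordinates and the fitted
    :class:`sklearn.decomposition.PCA` (no whitening).
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2:
        raise ValueError("expected a (n_samples, d_emb) matrix")
    n, d = vectors.shape
    if n_components > min(n, d):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, d_emb)={min(n, d)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full", whiten=False)
    reduced = pca.fit_transform(vectors)
    return reduced, pca


# ---------------------------------------------------------------------------
# embedding store
# ---------------------------------------------------------------------------
class EmbeddingStore:
    """Keyed HDF5 container for per-token matrices and per-protein vectors.

    Layout: one dataset per protein id under ``/per_token`` plus a single
    table (``/per_protein/values`` with an id index) for the pooled
    vectors, so individual samples can be read without loading the whole
    store.
    """

    def __init__(self, path: str | Path, mode: str = "r"):
        if mode not in ("r", "w", "a"):
            raise ValueError("mode must be one of 'r', 'w', 'a'")
        self._file = h5py.File(path, mode)
        self._protein_index: dict[str, int] | None = None
        if mode == "w":
            self._file.create_group("per_token")

    # -- context manager ------------------------------------------------------
    def __enter__(self) -> "EmbeddingStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def close(self) -> None:
        self._file.close()

    # -- per-token ------------------------------------------------------------
    def write_token(self, protein_id: str, matrix: np.ndarray) -> None:
        matrix = np.asarray(matrix)
        if matrix.ndim != 2:
            raise ValueError("per-token embedding must be 2-D")
        grp = self._file.require_group("per_token")
        if protein_id in grp:
            del grp[protein_id]
        grp.create_dataset(protein_id, data=matrix)
        self._file.attrs["d_emb"] = matrix.shape[1]

    def read_token(self, protein_id: str) -> np.ndarray:
        grp = self._file.get("per_token")
        if grp is None or protein_id not in grp:
            raise KeyError(f"no per-token embedding for id {protein_id!r}")
        return grp[protein_id][...]

    def token_ids(self) -> list[str]:
        grp = self._file.get("per_token")
        return sorted(grp.keys()) if grp is not None else []

    # -- per-protein ----------------------------------------------------------
    def write_protein_table(self, ids: Sequence[str], matrix: np.ndarray) -> None:
        matrix = np.asarray(matrix)
        if matrix.ndim != 2 or matrix.shape[0] != len(ids):
            raise ValueError("per-protein table must be (n_ids, d_emb)")
        grp = self._file.require_group("per_protein")
        for name in ("values", "ids"):
            if name in grp:
                del grp[name]
        grp.create_dataset("values", data=matrix)
        grp.create_dataset("ids", data=np.array(ids, dtype=h5py.string_dtype()))
        self._file.attrs["d_emb"] = matrix.shape[1]
        self._protein_index = None

    def _index(self) -> dict[str, int]:
        if self._protein_index is None:
            grp = self._file.get("per_protein")
            if grp is None:
                self._protein_index = {}
            else:
                ids = [s.decode() if isinstance(s, bytes) else s for s in grp["ids"][...]]
                self._protein_index = {pid: i for i, pid in enumerate(ids)}
        return self._protein_index

    def read_vector(self, protein_id: str) -> np.ndarray:
        idx = self._index()
        if protein_id not in idx:
            raise KeyError(f"no per-protein embedding for id {protein_id!r}")
        return self._file["per_protein"]["values"][idx[protein_id]]

    @property
    def d_emb(self) -> int:
        return int(self._file.attrs["d_emb"])
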