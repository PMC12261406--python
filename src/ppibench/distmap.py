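"""Comparison of implicit model maps with real inter-chain distance maps.

Map-exposing families form an ``(L1', L2')`` grid on the way to their
interaction score.  To test whether that grid carries structural
signal, it is compared against experimentally determined inter-chain
C-alpha distance maps: candidate pairs are filtered (confident
prediction, exactly two polymer entities, no homomers or extra
ligands, sufficient structural coverage), prediction sequences are
matched to structure sequences by Smith-Waterman local alignment, and
the Pearson correlation is computed over the aligned overlap.
"""

from __future__ import annotations

import dataclasses
import io as _io
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.PDB import PDBParser
from scipy.stats import pearsonr

__all__ = [
    "ChainStructure",
    "MapComparison",
    "AlignScoring",
    "CandidateEntry",
    "parse_structure",
    "real_distance_map",
    "local_align",
    "extract_predicted_map",
    "filter_candidates",
    "compare_maps",
    "map_comparison_pipeline",
]

# three-letter -> one-letter, with common modified residues folded to
# their parent standard amino acid; anything else becomes X
_AA_3TO1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
    # modified residues with a recognizable parent
    "MSE": "M", "SEP": "S", "TPO": "T", "PTR": "Y", "CSO": "C",
    "HYP": "P", "MLY": "K", "PCA": "Q", "KCX": "K", "CME": "C",
}


@dataclasses.dataclass
class ChainStructure:
    chain_id: str
    sequence: str
    ca_coords: np.ndarray  # (L, 3) Angstrom; NaN rows where unresolved
    resolved_mask: np.ndarray  # (L,) bool

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.ca_coords):
            raise ValueError("sequence and coordinate lengths differ")


@dataclasses.dataclass
class MapComparison:
    pearson_r: float  # NaN when degenerate
    n_overlap: int
    degenerate: bool
    real_values: np.ndarray
    predicted_values: np.ndarray


@dataclasses.dataclass
class AlignScoring:
    """Local-alignment scoring; BLOSUM62 with affine gaps by default."""

    matrix: str | None = "BLOSUM62"
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -11.0
    gap_extend: float = -1.0


def parse_structure(pdb_text: str) -> list[ChainStructure]:
    """First model of a PDB file as per-chain C-alpha traces.

    Residues without a C-alpha are kept in the sequence but flagged
    unresolved; altlocs resolve to the highest-occupancy atom (parser
    default); HETATM-only input raises.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("entry", _io.StringIO(pdb_text))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError("no ATOM records found in PDB text") from None
    chains: list[ChainStructure] = []
    for chain in model:
        seq: list[str] = []
        coords: list[np.ndarray] = []
        mask: list[bool] = []
        for residue in chain:
            if residue.id[0] != " ":  # skip HETATM / waters
                continue
            seq.append(_AA_3TO1.get(residue.get_resname().strip(), "X"))
            if "CA" in residue:
                coords.append(residue["CA"].get_coord().astype(float))
                mask.append(True)
            else:
                coords.append(np.full(3, np.nan))
                mask.append(False)
        if seq:
            chains.append(
                ChainStructure(
                    chain.id, "".join(seq), np.vstack(coords), np.array(mask)
                )
            )
    if not chains:
        raise ValueError("no ATOM records found in PDB text")
    return chains


def real_distance_map(c1: ChainStructure, c2: ChainStructure) -> np.ndarray:
    """Inter-chain C-alpha distances; NaN where a residue is unresolved."""
    if len(c1.sequence) == 0 or len(c2.sequence) == 0:
        raise ValueError("empty chain")
    diff = c1.ca_coords[:, None, :] - c2.ca_coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _build_aligner(scoring: AlignScoring) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    if scoring.matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    else:
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def local_align(
    query: str, target: str, scoring: AlignScoring | None = None
) -> tuple[list[tuple[int, int]], float]:
    """Smith-Waterman optimal local alignment.

    Returns gap-free matched index pairs (query position -> target
    position) and the alignment score (clipped at 0; empty mapping for
    hopeless pairs).
    """
    if not query or not target:
        raise ValueError("cannot align an empty sequence")
    scoring = scoring or AlignScoring()
    aligner = _build_aligner(scoring)
    score = float(aligner.score(query, target))
    if score <= 0:
        return [], 0.0
    alignment = aligner.align(query, target)[0]
    mapping: list[tuple[int, int]] = []
    q_blocks, t_blocks = alignment.aligned
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        mapping.extend(zip(range(qs, qe), range(ts, te)))
    return mapping, score


def extract_predicted_map(model, emb_a, emb_b) -> tuple[np.ndarray, float]:
    """One eval-mode forward pass -> (intermediate map, interaction score)."""
    if not getattr(model, "exposes_map", False):
        from .estimators import MapCapabilityError

        raise MapCapabilityError(
            f"{type(model).__name__} does not expose an intermediate map"
        )
    if hasattr(model, "predict_map") and not hasattr(model, "net_"):
        # synthetic mock models
        return model.predict_map(emb_a, emb_b)
    net = model.net_ if hasattr(model, "net_") else model
    net.eval()
    score, pair_map = net(emb_a, emb_b)
    return pair_map.data.copy(), float(score.data)


# ---------------------------------------------------------------------------
# candidate filtering
# ---------------------------------------------------------------------------
@dataclasses.dataclass
class CandidateEntry:
    """One confident prediction matched to a deposited structure."""

    pair: tuple[str, str]
    score: float
    structure_id: str
    n_polymer_entities: int
    has_extra_entities: bool  # ligands / cofactors flagged in metadata
    chain_sequences: tuple[str, str]  # structure chains matched to (A, B)
    query_sequences: tuple[str, str]  # prediction-side sequences


def filter_candidates(
    candidates: Sequence[CandidateEntry],
    confidence: float = 0.9,
    min_coverage: float = 0.4,
    scoring: AlignScoring | None = None,
) -> tuple[list[CandidateEntry], list[tuple[CandidateEntry, str]]]:
    """Apply the case-study inclusion rules; log every exclusion.

    Keeps entries with score strictly above ``confidence``, exactly two
    polymer entities and no extra ligands/cofactors, non-identical
    chain sequences (homomer check), and local-alignment coverage of at
    least ``min_coverage`` of each query sequence.
    """
    retained: list[CandidateEntry] = []
    excluded: list[tuple[CandidateEntry, str]] = []
    for entry in candidates:
        if not entry.score > confidence:
            excluded.append((entry, "low_confidence"))
            continue
        if entry.n_polymer_entities != 2 or entry.has_extra_entities:
            excluded.append((entry, "extra_entities"))
            continue
        if entry.chain_sequences[0] == entry.chain_sequences[1]:
            excluded.append((entry, "homomer"))
            continue
        coverage_ok = True
        for query, chain_seq in zip(entry.query_sequences, entry.chain_sequences):
            mapping, _ = local_align(query, chain_seq, scoring)
            if len(mapping) < min_coverage * len(query):
                coverage_ok = False
                break
        if not coverage_ok:
            excluded.append((entry, "low_coverage"))
            continue
        retained.append(entry)
    return retained, excluded


# ---------------------------------------------------------------------------
# map comparison
# ---------------------------------------------------------------------------
def compare_maps(
    predicted: np.ndarray,
    real: np.ndarray,
    index_map_1: Sequence[tuple[int, int]],
    index_map_2: Sequence[tuple[int, int]],
) -> MapComparison:
    """Pearson correlation over aligned, resolved positions.

    ``index_map_k`` maps prediction positions to structure positions on
    axis ``k``.  Cells whose structure residue is unresolved (NaN) are
    dropped; a constant overlap yields ``pearson_r = NaN`` with the
    ``degenerate`` flag set.
    """
    predicted = np.asarray(predicted, float)
    real = np.asarray(real, float)
    if len(index_map_1) < 2 or len(index_map_2) < 2:
        raise ValueError("need at least a 2x2 aligned overlap")
    p1, r1 = map(np.asarray, zip(*index_map_1))
    p2, r2 = map(np.asarray, zip(*index_map_2))
    if p1.max() >= predicted.shape[0] or p2.max() >= predicted.shape[1]:
        raise IndexError("alignment indexes outside the predicted map")
    if r1.max() >= real.shape[0] or r2.max() >= real.shape[1]:
        raise IndexError("alignment indexes outside the real map")
    pred_sub = predicted[np.ix_(p1, p2)].ravel()
    real_sub = real[np.ix_(r1, r2)].ravel()
    finite = np.isfinite(real_sub) & np.isfinite(pred_sub)
    pred_sub, real_sub = pred_sub[finite], real_sub[finite]
    n_overlap = int(finite.sum())
    if n_overlap < 2:
        raise ValueError("fewer than 2 finite aligned cells")
    if np.ptp(pred_sub) == 0 or np.ptp(real_sub) == 0:
        return MapComparison(float("nan"), n_overlap, True, real_sub, pred_sub)
    r = float(pearsonr(pred_sub, real_sub).statistic)
    return MapComparison(r, n_overlap, False, real_sub, pred_sub)


def map_comparison_pipeline(
    model,
    emb_a: np.ndarray,
    emb_b: np.ndarray,
    query_sequences: tuple[str, str],
    pdb_text: str,
    scoring: AlignScoring | None = None,
) -> MapComparison:
    """Predict, parse, align both axes, and correlate — one pair end to end.

    The predicted map is generally smaller than ``L1 x L2`` (convolution
    arithmetic); alignment indices beyond its edge are cropped.
    """
    pred_map, _ = extract_predicted_map(model, emb_a, emb_b)
    chains = parse_structure(pdb_text)
    if len(chains) < 2:
        raise ValueError("structure does not contain two chains")
    c1, c2 = chains[0], chains[1]
    real = real_distance_map(c1, c2)
    map1, _ = local_align(query_sequences[0], c1.sequence, scoring)
    map2, _ = local_align(query_sequences[1], c2.sequence, scoring)
    map1 = [(q, t) for q, t in map1 if q < pred_map.shape[0]]
    map2 = [(q, t) for q, t in map2 if q < pred_map.shape[1]]
    return compare_maps(pred_map, real, map1, map2)
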