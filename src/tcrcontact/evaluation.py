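"""Evaluation metrics: discrimination and explanation quality.

Two metric families:

* partial ROC-AUC restricted to low false-positive rates (default cap 0.1),
  McClish-standardized so chance reads 0.5 and perfection 1.0 — the regime
  that matters when candidate binders are triaged for experiments;
* the Binding Region Hit Rate (BRHR): the overlap between the top-t fraction
  of residues ranked by the model's contact scores and the top-t fraction
  ranked by structure-derived proximity (smallest residue-to-nearest-atom
  distance), computed per positive sample and direction.

Also here: ground-truth distance extraction from PDB structures and the
center-aligned averaging of contact maps used to visualize class-level
contact patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score

from .errors import StructureSelectionError, UndefinedMetricError
from .layers import ContactMap

#: the four explanation directions
DIRECTIONS = ("pep->cdr3a", "pep->cdr3b", "cdr3a->pep", "cdr3b->pep")


@dataclass(frozen=True)
class DistanceMap:
    """Per-residue distances (Å) from each source residue to the nearest
    atom of the partner selection, for one direction."""

    direction: str
    distances: np.ndarray
    source_ids: tuple = ()

    def __post_init__(self):
        d = np.asarray(self.distances, dtype=np.float64)
        object.__setattr__(self, "distances", d)
        if d.ndim != 1:
            raise ValueError("distances must be a vector")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class BrhrResult:
    direction: str
    threshold: float
    hit_rate: float
    n_selected: int


# ---------------------------------------------------------------------------
# structure-derived ground truth


def _select(atoms, chain_id: str, res_range: Optional[tuple] = None):
    m = atoms.chain_id == chain_id
    if res_range is not None:
        lo, hi = res_range
        m &= (atoms.res_id >= lo) & (atoms.res_id <= hi)
    sel = atoms[m]
    if sel.array_length() == 0:
        raise StructureSelectionError(
            f"no atoms for chain {chain_id!r} range {res_range!r}")
    return sel


def _per_residue_min(src, partner) -> tuple[np.ndarray, tuple]:
    """Min Euclidean distance from each residue of `src` to any partner atom."""
    res_ids = np.unique(src.res_id)
    dists = np.empty(res_ids.size)
    for i, rid in enumerate(res_ids):
        coords = src.coord[src.res_id == rid]
        dists[i] = cdist(coords, partner.coord).min()
    return dists, tuple(int(r) for r in res_ids)


def residue_distances(structure_path, peptide_chain: str,
                      cdr3a_range: tuple, cdr3b_range: tuple,
                      model: int = 1) -> dict[str, DistanceMap]:
    """Extract all four directional distance maps from a PDB structure.

    ``cdr3a_range``/``cdr3b_range`` are (chain_id, first_res_id, last_res_id)
    in author numbering. Hydrogens are excluded and the first alternate
    location of each atom is used. Missing residues inside a range are simply
    absent from the returned ``source_ids`` (callers can diff against the
    requested interval).
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(structure_path))
    atoms = pdb.get_structure(model=model, altloc="first")
    atoms = atoms[atoms.element != "H"]

    pep = _select(atoms, peptide_chain)
    a_chain, a_lo, a_hi = cdr3a_range
    b_chain, b_lo, b_hi = cdr3b_range
    cdr3a = _select(atoms, a_chain, (a_lo, a_hi))
    cdr3b = _select(atoms, b_chain, (b_lo, b_hi))

    out = {}
    for direction, src, partner in (
            ("pep->cdr3a", pep, cdr3a), ("pep->cdr3b", pep, cdr3b),
            ("cdr3a->pep", cdr3a, pep), ("cdr3b->pep", cdr3b, pep)):
        d, ids = _per_residue_min(src, partner)
        out[direction] = DistanceMap(direction=direction, distances=d,
                                     source_ids=ids)
    return out


# ---------------------------------------------------------------------------
# residue importance and BRHR


def residue_importance(cmap: ContactMap, direction: str, *,
                       reduction: str = "max") -> np.ndarray:
    """Per-residue contact scores for one direction of a contact map.

    The score of a source residue is the max (default; ``reduction="mean"``
    available) of A′ over valid partner positions — mirroring the
    nearest-atom (min-distance) convention of the ground truth. The source
    axis is the map's row axis for ``pep->*`` directions and its column axis
    for ``*->pep``.
    """
    src, dst = direction.split("->")
    if src == "pep":
        if cmap.row_axis != "peptide" or cmap.col_axis != dst:
            raise ValueError(f"map with axes ({cmap.row_axis}, {cmap.col_axis}) "
                             f"cannot serve direction {direction!r}")
        block = cmap.area[:cmap.row_length, :cmap.col_length]
    else:
        if cmap.col_axis != src or cmap.row_axis != "peptide":
            raise ValueError(f"map with axes ({cmap.row_axis}, {cmap.col_axis}) "
                             f"cannot serve direction {direction!r}")
        block = cmap.area[:cmap.row_length, :cmap.col_length].T
    if block.size == 0:
        return np.zeros(0)
    if reduction == "max":
        return block.max(axis=1)
    if reduction == "mean":
        return block.mean(axis=1)
    raise ValueError(f"unknown reduction {reduction!r}")


def _top_k_indices(values: np.ndarray, k: int, largest: bool) -> set:
    """Indices of the k most extreme values; ties broken by ascending index."""
    order = np.argsort(-values if largest else values, kind="stable")
    return set(int(i) for i in order[:k])


def brhr(scores: np.ndarray, distances: DistanceMap,
         t: float = 0.25) -> BrhrResult:
    """Binding Region Hit Rate at percentile threshold ``t``.

    With L residues, k = max(1, ⌈t·L⌉) — so every case contributes at least
    one contact residue. The hit set is the intersection of the k
    highest-score residues and the k structurally closest residues;
    hit_rate = |intersection| / k.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != distances.distances.shape:
        raise ValueError(f"scores length {scores.shape} != distances length "
                         f"{distances.distances.shape}")
    if not 0 < t <= 1:
        raise ValueError("t must lie in (0, 1]")
    L = scores.size
    k = max(1, math.ceil(t * L))
    top_scores = _top_k_indices(scores, k, largest=True)
    top_close = _top_k_indices(distances.distances, k, largest=False)
    hits = len(top_scores & top_close)
    return BrhrResult(direction=distances.direction, threshold=t,
                      hit_rate=hits / k, n_selected=k)


# ---------------------------------------------------------------------------
# partial ROC-AUC


def partial_auc(y_score, y_true, max_fpr: float = 0.1) -> float:
    """ROC-AUC restricted to FPR ∈ [0, max_fpr], McClish-standardized.

    A perfect ranking scores 1.0 and an uninformative one 0.5 regardless of
    ``max_fpr``; at ``max_fpr=1`` this is the ordinary ROC-AUC.
    """
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=np.float64)
    if not 0 < max_fpr <= 1:
        raise ValueError("max_fpr must lie in (0, 1]")
    if np.unique(y_true).size < 2:
        raise UndefinedMetricError("partial AUC needs both classes present")
    return float(roc_auc_score(y_true, y_score, max_fpr=max_fpr))


# ---------------------------------------------------------------------------
# center-aligned aggregation


def center_align_average(maps: Sequence[ContactMap],
                         n: Optional[int] = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Average contact maps with valid blocks aligned at the grid center.

    Each map's valid L₁×L₂ block is placed at offset ⌊(N−L)/2⌋ per axis;
    cells outside a map's placed block contribute 0 to that map's layer.
    Returns (mean, elementwise variance), each N×N.
    """
    if not maps:
        raise ValueError("no maps to average")
    if n is None:
        n = maps[0].area.shape[0]
    stack = np.zeros((len(maps), n, n))
    for i, m in enumerate(maps):
        l1, l2 = m.row_length, m.col_length
        r0 = (n - l1) // 2
        c0 = (n - l2) // 2
        stack[i, r0:r0 + l1, c0:c0 + l2] = m.area[:l1, :l2]
    return stack.mean(axis=0), stack.var(axis=0)


def class_averaged_maps(maps: Sequence[ContactMap], y_hat: Sequence[float],
                        threshold: float = 0.5,
                        n: Optional[int] = None) -> dict:
    """Center-aligned mean/variance maps grouped by predicted class.

    ``threshold`` is applied to ŷ; because the head's scores are small by
    construction (w ≤ max A′), a rank-based threshold such as the score
    median is often more useful — pass it explicitly.
    """
    y_hat = np.asarray(y_hat, dtype=np.float64)
    out = {}
    for name, mask in (("positive", y_hat >= threshold),
                       ("negative", y_hat < threshold)):
        group = [m for m, keep in zip(maps, mask) if keep]
        if group:
            mean, var = center_align_average(group, n)
            out[name] = {"mean": mean, "variance": var, "count": len(group)}
    return out
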