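"""Paired-chain TCR-pMHC triplet datasets.

A dataset is a list of :class:`TriadRecord` — one CDR3α / CDR3β / peptide
triplet with a binary binding label and an epitope identity. This module
reads and validates delimited text, augments positives with shuffled
negatives at a configurable ratio, and builds unseen-epitope train/test
splits guarded by a minimum Levenshtein distance between test and train
peptides.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyDatasetError, InfeasibleSplitError

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

_LOGICAL_COLUMNS = ("cdr3a", "cdr3b", "peptide")


@dataclass(frozen=True)
class TriadRecord:
    """One CDR3α/CDR3β/peptide triplet; the unit of training and evaluation."""

    cdr3a: str
    cdr3b: str
    peptide: str
    label: int = 1
    epitope_id: str = ""
    source: str = ""
    mhc_class: str = "unknown"

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if not self.epitope_id:
            object.__setattr__(self, "epitope_id", self.peptide)

    @property
    def triple(self) -> tuple:
        return (self.cdr3a, self.cdr3b, self.peptide)


@dataclass(frozen=True)
class SplitSpec:
    """Parameters of an unseen-epitope split."""

    min_edit_distance: int = 3
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.min_edit_distance < 0:
            raise ValueError("min_edit_distance must be non-negative")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


def levenshtein(a: str, b: str) -> int:
    """Edit distance between two sequences (insert/delete/substitute)."""
    return edlib.align(a, b, task="distance")["editDistance"]


def _is_standard(seq: str) -> bool:
    return len(seq) > 0 and set(seq) <= STANDARD_AA


def read_triads(path, column_map: Optional[dict] = None, *, sep: str = ",",
                require_label: bool = True) -> list[TriadRecord]:
    """Read triplet records from delimited text.

    ``column_map`` maps logical names (``cdr3a``, ``cdr3b``, ``peptide``,
    ``label``, ``epitope_id``, ``source``, ``mhc_class``) to the file's
    column names; identity mapping by default. Sequences are uppercased
    before validation, and rows containing characters outside the 20
    standard amino-acid codes (or empty sequences) are dropped; the number
    of dropped rows is logged — use :func:`read_triads_report` to receive
    it programmatically.
    """
    records, _ = read_triads_report(path, column_map, sep=sep,
                                    require_label=require_label)
    return records


def read_triads_report(path, column_map: Optional[dict] = None, *,
                       sep: str = ",", require_label: bool = True
                       ) -> tuple[list[TriadRecord], int]:
    """Like :func:`read_triads` but also returns the dropped-row count."""
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    def col(logical, required=True):
        name = column_map.get(logical, logical)
        if name not in df.columns:
            if required:
                raise ConfigurationError(
                    f"column {name!r} (logical {logical!r}) not found in {path}")
            return None
        return name

    seq_cols = {k: col(k) for k in _LOGICAL_COLUMNS}
    label_col = col("label", required=require_label)
    epi_col = col("epitope_id", required=False)
    src_col = col("source", required=False)
    mhc_col = col("mhc_class", required=False)

    records: list[TriadRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        seqs = {k: str(row[seq_cols[k]]).strip().upper() for k in _LOGICAL_COLUMNS}
        if not all(_is_standard(s) for s in seqs.values()):
            dropped += 1
            continue
        label = 1
        if label_col is not None and str(row.get(label_col, "")).strip() != "":
            try:
                label = int(float(row[label_col]))
            except ValueError:
                dropped += 1
                continue
            if label not in (0, 1):
                dropped += 1
                continue
        records.append(TriadRecord(
            cdr3a=seqs["cdr3a"], cdr3b=seqs["cdr3b"], peptide=seqs["peptide"],
            label=label,
            epitope_id=str(row[epi_col]).strip() if epi_col else "",
            source=str(row[src_col]).strip() if src_col else "",
            mhc_class=str(row[mhc_col]).strip() or "unknown" if mhc_col else "unknown",
        ))
    if dropped:
        logger.info("read_triads: dropped %d of %d rows failing sequence/label "
                    "validation", dropped, len(df))
    if not records:
        raise EmptyDatasetError(f"no valid records in {path}")
    return records, dropped


def write_triads(records: Sequence[TriadRecord], path, *, sep: str = ",") -> None:
    """Write records back to delimited text with a provenance column."""
    rows = [{
        "cdr3a": r.cdr3a, "cdr3b": r.cdr3b, "peptide": r.peptide,
        "label": r.label, "epitope_id": r.epitope_id, "source": r.source,
        "mhc_class": r.mhc_class,
        "provenance": "positive" if r.label == 1 else "shuffled-negative",
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def generate_negatives(positives: Sequence[TriadRecord], ratio: float,
                       seed: int, *, max_retries: int = 100
                       ) -> list[TriadRecord]:
    """Create mismatched negatives by moving paired TCR chains across epitopes.

    For each epitope, ``floor(ratio * n_positives)`` negatives are drawn: the
    epitope keeps its peptide, while the paired (cdr3a, cdr3b) chains come
    from a record of a *different* epitope. A draw that reproduces a known
    positive triple is rejected and retried up to ``max_retries`` times;
    any shortfall is logged. Deterministic under ``seed``.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    positives = [r for r in positives if r.label == 1]
    by_epitope: dict[str, list[TriadRecord]] = {}
    for r in positives:
        by_epitope.setdefault(r.epitope_id, []).append(r)
    if len(by_epitope) < 2:
        raise ValueError("negative generation needs at least two distinct epitopes")

    positive_triples = {r.triple for r in positives}
    rng = np.random.default_rng(seed)
    negatives: list[TriadRecord] = []
    for epitope in sorted(by_epitope):
        own = by_epitope[epitope]
        peptide = own[0].peptide
        donors = [r for r in positives if r.epitope_id != epitope]
        n_wanted = math.floor(ratio * len(own))
        emitted = 0
        for _ in range(n_wanted):
            for _attempt in range(max_retries):
                donor = donors[rng.integers(len(donors))]
                triple = (donor.cdr3a, donor.cdr3b, peptide)
                if triple not in positive_triples:
                    negatives.append(TriadRecord(
                        cdr3a=donor.cdr3a, cdr3b=donor.cdr3b, peptide=peptide,
                        label=0, epitope_id=epitope, source="shuffled",
                        mhc_class=own[0].mhc_class))
                    emitted += 1
                    break
        if emitted < n_wanted:
            logger.warning("epitope %s: only %d of %d negatives could be drawn "
                           "without colliding with positives", epitope, emitted,
                           n_wanted)
    return negatives


def unseen_epitope_split(records: Sequence[TriadRecord], spec: SplitSpec
                         ) -> tuple[list[TriadRecord], list[TriadRecord]]:
    """Split records so that test epitopes are unseen and dissimilar.

    An epitope is *eligible* for the test side when its minimal Levenshtein
    distance to every other epitope exceeds ``spec.min_edit_distance``;
    eligible epitopes are then sampled to approximate ``spec.test_fraction``
    of all epitopes. Because eligibility is measured against every other
    epitope, the test/train distance guarantee holds by construction.
    """
    epitopes = sorted({r.epitope_id for r in records})
    if len(epitopes) < 2:
        raise ValueError("split needs at least two distinct epitopes")
    peptide_of = {}
    for r in records:
        peptide_of.setdefault(r.epitope_id, r.peptide)

    eligible = []
    for e in epitopes:
        dmin = min(levenshtein(peptide_of[e], peptide_of[q])
                   for q in epitopes if q != e)
        if dmin > spec.min_edit_distance:
            eligible.append(e)
    if not eligible:
        raise InfeasibleSplitError(
            f"no epitope has minimal pairwise edit distance > "
            f"{spec.min_edit_distance}")

    n_test = max(1, round(spec.test_fraction * len(epitopes)))
    n_test = min(n_test, len(eligible), len(epitopes) - 1)
    rng = np.random.default_rng(spec.seed)
    test_epitopes = set(rng.choice(eligible, size=n_test, replace=False))

    train = [r for r in records if r.epitope_id not in test_epitopes]
    test = [r for r in records if r.epitope_id in test_epitopes]
    return train, test


def unique_sequences(records: Iterable[TriadRecord]) -> list[str]:
    """All distinct CDR3α, CDR3β, and peptide sequences, sorted."""
    seqs = set()
    for r in records:
        seqs.update(r.triple)
    return sorted(seqs)
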