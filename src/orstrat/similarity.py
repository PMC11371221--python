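"""Protein similarity search and best-hit reduction.

Two interchangeable hit sources feed the phylostratigraphy stage:

* externally computed BLAST tabular files (read via
  :func:`orstrat.sequence_io.read_blast_tab`), and
* a built-in deterministic Smith–Waterman search (:func:`search`) so that
  synthetic pipelines run with no external tool.

E-values for the built-in search use the Karlin–Altschul form
``E = K * m * n * exp(-lambda * S)`` with fixed gapped-BLOSUM62 convention
constants; only threshold-crossing behaviour matters downstream, so
determinism is preferred over fidelity to any particular BLAST build.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .sequence_io import SeqRecord

logger = logging.getLogger("orstrat")

#: Karlin–Altschul constants, gapped BLOSUM62 convention.
KA_K = 0.041
KA_LAMBDA = 0.267

#: Affine gap penalties (BLAST convention: a gap of length L costs
#: gap_open + gap_extend * L).
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1


@dataclass(frozen=True)
class HitRecord:
    """One query-subject similarity record."""

    query_id: str
    subject_id: str
    subject_species: str
    evalue: float
    bitscore: float
    pident: float = 0.0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.query_id}->{self.subject_id}")
        if not self.subject_species:
            raise ValueError(f"empty subject species for subject {self.subject_id!r}")


@dataclass
class HitTable:
    """A list of hit records, optionally stamped with the e-value threshold
    that was applied to produce it."""

    records: list[HitRecord]
    threshold_applied: float | None = None

    def __post_init__(self) -> None:
        if self.threshold_applied is not None:
            over = [r for r in self.records if r.evalue > self.threshold_applied]
            if over:
                raise ValueError(
                    f"{len(over)} records exceed the declared threshold "
                    f"{self.threshold_applied}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def queries(self) -> set[str]:
        return {r.query_id for r in self.records}

    def sorted(self) -> "HitTable":
        """Canonical record order (query, species, evalue, subject)."""
        key = lambda r: (r.query_id, r.subject_species, r.evalue, -r.bitscore, r.subject_id)
        return HitTable(sorted(self.records, key=key), self.threshold_applied)


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    try:
        sub = substitution_matrices.load(matrix)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {matrix!r}") from exc
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = sub
    aligner.mode = "local"
    # Biopython charges open_gap_score on the first gap residue; the BLAST
    # convention cost(L) = open + extend*L maps to open+extend then extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def local_align_score(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> int:
    """Optimal Smith–Waterman local alignment score under affine gaps.

    A gap of length L costs ``gap_open + gap_extend * L``. The score of the
    empty alignment is 0, so the result is never negative. Deterministic.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    return int(aligner.score(a, b))


def score_to_evalue(
    score: float, m: int, n: int, K: float = KA_K, lam: float = KA_LAMBDA,
) -> float:
    """Karlin–Altschul expect value ``E = K * m * n * exp(-lambda * score)``.

    *m* is the query length, *n* the total database length.
    """
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    if K <= 0 or lam <= 0:
        raise ValueError("K and lambda must be positive")
    return K * m * n * math.exp(-lam * score)


def search(
    queries: Sequence[SeqRecord],
    subjects: Sequence[SeqRecord],
    species_of: Mapping[str, str],
    evalue_threshold: float = 1e-5,
    matrix: str = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> HitTable:
    """Score every query x subject pair and retain hits with E <= threshold.

    The database length *n* in the e-value is the summed subject length, as
    in a BLAST database search. Output record order is canonical (sorted),
    so it is invariant under permutation of the subject list.
    """
    if evalue_threshold <= 0:
        raise ValueError("evalue_threshold must be > 0")
    if not subjects:
        logger.warning("empty subject set: search returns no hits")
        return HitTable(records=[], threshold_applied=evalue_threshold)
    missing = [s.id for s in subjects if s.id not in species_of]
    if missing:
        raise ValueError(f"subjects missing from species map: {missing[:5]}")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    db_len = sum(len(s.residues) for s in subjects)
    records: list[HitRecord] = []
    for q in queries:
        for s in subjects:
            score = int(aligner.score(q.residues, s.residues))
            evalue = score_to_evalue(score, len(q.residues), db_len)
            if evalue <= evalue_threshold:
                # bit score under the same constants: S' = (lambda*S - ln K)/ln 2
                bits = (KA_LAMBDA * score - math.log(KA_K)) / math.log(2)
                records.append(HitRecord(
                    query_id=q.id, subject_id=s.id,
                    subject_species=species_of[s.id],
                    evalue=evalue, bitscore=round(bits, 1),
                ))
    return HitTable(records, threshold_applied=evalue_threshold).sorted()


def best_hit_per_species(hits: HitTable, rank_by: str = "evalue") -> HitTable:
    """Reduce a hit table to one record per (query, subject species).

    ``rank_by="evalue"`` keeps the record with the lowest e-value (ties
    broken by higher bitscore, then lexicographic subject id).
    ``rank_by="pident"`` keeps the highest percent identity instead (the
    convention used when associating receptor sequences to reference
    proteins), with the same tie-breaking cascade after identity.
    Idempotent.
    """
    if rank_by not in ("evalue", "pident"):
        raise ValueError(f"rank_by must be 'evalue' or 'pident', got {rank_by!r}")
    best: dict[tuple[str, str], HitRecord] = {}
    for r in hits.records:
        key = (r.query_id, r.subject_species)
        cur = best.get(key)
        if cur is None or _better(r, cur, rank_by):
            best[key] = r
    return HitTable(list(best.values()), hits.threshold_applied).sorted()


def _better(a: HitRecord, b: HitRecord, rank_by: str) -> bool:
    """True if record *a* outranks *b* under the chosen ranking."""
    if rank_by == "pident":
        ka = (-a.pident, a.evalue, -a.bitscore, a.subject_id)
        kb = (-b.pident, b.evalue, -b.bitscore, b.subject_id)
    else:
        ka = (a.evalue, -a.bitscore, a.subject_id)
        kb = (b.evalue, -b.bitscore, b.subject_id)
    return ka < kb
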