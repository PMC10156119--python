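"""Explaining off-target binding: abundance, homology, or promiscuity.

Every off-target event (an antibody capturing a receptor other than its
intended target) is annotated with two candidate causes: the off-target was
present at much higher abundance than the intended target (expression ratio
off/on at or above twofold), or the antibody's antigen is genuinely similar
in sequence to the off-target protein (Smith-Waterman local alignment with
Karlin-Altschul E-value below 1).  Events explained by neither are deemed
*promiscuous*.  Replicate consistency records whether the off-target was
captured in every QC-passing sample containing it.

E = K * m * n * exp(-lambda * S) with (K, lambda) fixed configuration
constants for the chosen matrix/gap setting; E < 1 is a permissive homology
boundary (a best-scoring chance alignment has E of order 1), which suits its
role here as an explanatory flag rather than a homology search statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .core import AA_ALPHABET

# Karlin-Altschul parameters for BLOSUM62 with affine gap cost 11 + L
# (protein-search convention); configuration constants, not fit to data.
LAMBDA = 0.267
KAPPA = 0.041


@dataclass
class AlignmentResult:
    score: float
    e_value: float
    aligned_span_query: tuple  # 1-based inclusive
    aligned_span_subject: tuple
    identity_fraction: float


@dataclass
class CrossReactRecord:
    antibody_id: str
    on_target: str
    off_target: str
    expression_ratio: float  # off / on, linear scale; NaN = not computable
    e_value: float
    n_samples_above: int
    cause_flags: set = field(default_factory=set)
    consistent: bool = False


def _check_protein(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    bad = sorted(set(seq) - AA_ALPHABET)
    if bad:
        raise ValueError(f"illegal residue(s) {bad} in {name} sequence")


def make_aligner(matrix: str = "BLOSUM62", gap_open: float = 11.0, gap_extend: float = 1.0):
    """Local aligner with affine gap cost ``gap_open + L * gap_extend``."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(
    query: str,
    subject: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    lam: float = LAMBDA,
    kappa: float = KAPPA,
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment with an analytic E-value.

    A gap of length L costs ``gap_open + L * gap_extend``.  The E-value is
    Karlin-Altschul, E = K * m * n * exp(-lambda * S), with m, n the sequence
    lengths and S the raw alignment score.
    """
    _check_protein(query, "query")
    _check_protein(subject, "subject")
    aligner = make_aligner(matrix, gap_open, gap_extend)
    alignment = aligner.align(query, subject)[0]
    score = float(alignment.score)
    q_blocks, s_blocks = alignment.aligned
    q_span = (int(q_blocks[0][0]) + 1, int(q_blocks[-1][1]))
    s_span = (int(s_blocks[0][0]) + 1, int(s_blocks[-1][1]))
    counts = alignment.counts()
    aligned_cols = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / aligned_cols if aligned_cols else 0.0
    e_value = kappa * len(query) * len(subject) * math.exp(-lam * score)
    return AlignmentResult(
        score=score,
        e_value=e_value,
        aligned_span_query=q_span,
        aligned_span_subject=s_span,
        identity_fraction=float(identity),
    )


def expression_ratio(expr_results, on_id: str, off_id: str) -> float:
    """Off / on ratio of mean linear-scale tag-capture levels.

    NaN flags a non-computable ratio (on-target unsupported or at zero), so
    the abundance cause can never fire for it.
    """
    by_id = {r.gpcr_id: r for r in expr_results}
    on = by_id.get(on_id)
    off = by_id.get(off_id)
    if on is None or off is None:
        return math.nan
    if on.status != "supported" or not on.mean_linear or math.isnan(on.mean_linear):
        return math.nan
    return off.mean_linear / on.mean_linear


def annotate_cause(record: CrossReactRecord, ratio_cut: float = 2.0, evalue_cut: float = 1.0) -> CrossReactRecord:
    """Set cause flags: abundance (ratio >= cut), homology (E < cut), else promiscuous."""
    flags = set()
    if not math.isnan(record.expression_ratio) and record.expression_ratio >= ratio_cut:
        flags.add("abundance")
    if record.e_value < evalue_cut:
        flags.add("homology")
    if not flags:
        flags.add("promiscuous")
    record.cause_flags = flags
    return record


def replicate_consistency(record: CrossReactRecord, profile, samples) -> CrossReactRecord:
    """Consistent iff every QC-passing sample containing the off-target is above threshold."""
    threshold = profile.threshold
    rz = profile.rz.dropna()
    off_ids = [
        s.sample_id
        for s in samples
        if s.construct == record.off_target and s.sample_id in rz.index
    ]
    n_above = int(sum(rz[sid] > threshold for sid in off_ids))
    record.n_samples_above = n_above
    record.consistent = bool(off_ids) and n_above == len(off_ids)
    return record


def deconvolve(
    annotations,
    profiles: dict,
    expr_results,
    library,
    antibodies,
    samples,
    ratio_cut: float = 2.0,
    evalue_cut: float = 1.0,
) -> list:
    """One :class:`CrossReactRecord` per (antibody, off-target) event.

    The alignment query is the antibody's antigen sequence (the immunogen
    fragment), not the full on-target protein; the subject is the full
    cross-captured protein sequence.
    """
    lib = {g.gpcr_id: g for g in library}
    ab_by_id = {ab.antibody_id: ab for ab in antibodies}
    records = []
    for ann in annotations:
        if not ann.offtarget_events:
            continue
        ab = ab_by_id[ann.antibody_id]
        target = lib[ab.target_id]
        if ab.antigen_start is None:
            antigen = target.sequence
        else:
            antigen = target.sequence[ab.antigen_start - 1 : ab.antigen_end]
        for ev in ann.offtarget_events:
            aln = local_align(antigen, lib[ev.gpcr_id].sequence)
            rec = CrossReactRecord(
                antibody_id=ann.antibody_id,
                on_target=ab.target_id,
                off_target=ev.gpcr_id,
                expression_ratio=expression_ratio(expr_results, ab.target_id, ev.gpcr_id),
                e_value=aln.e_value,
                n_samples_above=ev.n_samples_above,
            )
            annotate_cause(rec, ratio_cut=ratio_cut, evalue_cut=evalue_cut)
            replicate_consistency(rec, profiles[ann.antibody_id], samples)
            records.append(rec)
    return records


def events_table(records) -> pd.DataFrame:
    """Flat TSV-ready table, one row per (antibody, off-target) event."""
    rows = [
        {
            "antibody_id": r.antibody_id,
            "on_target": r.on_target,
            "off_target": r.off_target,
            "expression_ratio": r.expression_ratio,
            "e_value": r.e_value,
            "n_samples_above": r.n_samples_above,
            "abundance": "abundance" in r.cause_flags,
            "homology": "homology" in r.cause_flags,
            "promiscuous": "promiscuous" in r.cause_flags,
            "consistent": r.consistent,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "antibody_id",
            "on_target",
            "off_target",
            "expression_ratio",
            "e_value",
            "n_samples_above",
            "abundance",
            "homology",
            "promiscuous",
            "consistent",
        ],
    )
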