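"""Data model and file I/O for multiplexed suspension-bead-array (SBA) panels.

An SBA screen measures, per well (sample) and per color-coded bead population
(one antibody each), a median fluorescence intensity (MFI) together with the
number of bead events behind it.  This module defines the panel metadata
records (antibodies, receptor constructs, samples), the paired MFI/bead-count
matrix container, and the plain-text readers/writers the rest of the package
builds on.  All tabular files are TSV with a header row; sequences travel as
FASTA.

Coordinate convention: antigen spans are 1-based inclusive residue positions
on the untagged native receptor sequence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SUBFAMILIES = (
    "rhodopsin_alpha",
    "rhodopsin_beta",
    "rhodopsin_gamma",
    "rhodopsin_delta",
    "GSAF",
    "other",
)

#: Reserved construct token for empty-vector (negative-control) lysates.
MOCK = "MOCK"

#: Recognised non-GPCR bead roles (epitope-tag capture and coupling control).
CONTROL_ROLES = ("anti-FLAG", "anti-HA", "anti-1D4", "coupling-control")

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


class PanelValidationError(ValueError):
    """Structured validation failure; carries the list of offending items."""

    def __init__(self, message: str, offenders: Sequence[str] = ()):
        self.offenders = list(offenders)
        if self.offenders:
            message = f"{message}: {', '.join(map(str, self.offenders))}"
        super().__init__(message)


@dataclass(frozen=True)
class AntibodyRecord:
    """One antibody-coupled bead population of a subfamily panel."""

    antibody_id: str
    bead_id: int
    target_id: str  # GPCR gene symbol, or one of CONTROL_ROLES
    subfamily_panel: str
    antigen_start: int | None = None
    antigen_end: int | None = None
    source: str = ""

    def __post_init__(self):
        if self.subfamily_panel not in SUBFAMILIES:
            raise PanelValidationError("unknown subfamily panel", [self.subfamily_panel])
        if self.is_control and (self.antigen_start is not None or self.antigen_end is not None):
            raise PanelValidationError("control bead must not carry an antigen span", [self.antibody_id])
        if (self.antigen_start is None) != (self.antigen_end is None):
            raise PanelValidationError("antigen span must give both start and end", [self.antibody_id])
        if self.antigen_start is not None:
            if self.antigen_start < 1 or self.antigen_end < self.antigen_start:
                raise PanelValidationError(
                    "antigen span must satisfy 1 <= start <= end", [self.antibody_id]
                )

    @property
    def is_control(self) -> bool:
        return self.target_id in CONTROL_ROLES


@dataclass(frozen=True)
class GPCRRecord:
    """An epitope-tagged receptor construct of the expression library.

    Constructs carry an N-terminal capture tag (FLAG, or HA for frizzled
    receptors) and the constant C-terminal 1D4 detection tag.
    """

    gpcr_id: str
    subfamily: str
    sequence: str
    n_tag: str = "FLAG"
    c_tag: str = "1D4"
    orphan: bool = False

    def __post_init__(self):
        if self.subfamily not in SUBFAMILIES:
            raise PanelValidationError("unknown subfamily", [self.subfamily])
        if self.n_tag not in ("FLAG", "HA"):
            raise PanelValidationError("n_tag must be FLAG or HA", [self.gpcr_id])
        if not self.sequence:
            raise PanelValidationError("empty sequence", [self.gpcr_id])
        bad = sorted(set(self.sequence) - AA_ALPHABET)
        if bad:
            raise PanelValidationError(
                f"illegal residue(s) {bad} in sequence of", [self.gpcr_id]
            )


@dataclass(frozen=True)
class SampleRecord:
    """One assay well: a lysate expressing one construct (or mock)."""

    sample_id: str
    construct: str  # gpcr_id or MOCK
    bio_replicate: int
    tech_replicate: int
    panel: str

    def __post_init__(self):
        if self.panel not in SUBFAMILIES:
            raise PanelValidationError("unknown panel", [self.panel])

    @property
    def is_mock(self) -> bool:
        return self.construct == MOCK


@dataclass
class AssayMatrix:
    """Paired samples x beads MFI and bead-count matrices.

    ``mfi`` may contain NaN for cells masked by QC; raw input must be finite
    and non-negative.  ``bead_count`` holds non-negative integers.
    """

    mfi: pd.DataFrame
    bead_count: pd.DataFrame

    def __post_init__(self):
        if not self.mfi.index.equals(self.bead_count.index) or not self.mfi.columns.equals(
            self.bead_count.columns
        ):
            raise PanelValidationError("MFI and bead-count matrices must share rows and columns")
        vals = self.mfi.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise PanelValidationError("MFI values must be finite")
        if np.nanmin(vals, initial=0.0) < 0:
            raise PanelValidationError("MFI values must be non-negative")
        counts = self.bead_count.to_numpy()
        if (counts < 0).any():
            raise PanelValidationError("bead counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.mfi.index)

    @property
    def beads(self) -> list[int]:
        return list(self.mfi.columns)

    def copy(self) -> "AssayMatrix":
        return AssayMatrix(self.mfi.copy(), self.bead_count.copy())


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_panel`; lists every violation found."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


# ---------------------------------------------------------------------------
# TSV / FASTA readers and writers
# ---------------------------------------------------------------------------

_BEAD_PREFIX = "bead_"


def _bead_col(bead_id: int) -> str:
    return f"{_BEAD_PREFIX}{bead_id}"


def write_mfi_table(matrix: AssayMatrix, mfi_path, counts_path) -> None:
    """Write the paired MFI (1 decimal place) and bead-count TSVs."""
    mfi = matrix.mfi.copy()
    mfi.columns = [_bead_col(b) for b in mfi.columns]
    mfi.index.name = "sample_id"
    mfi.to_csv(mfi_path, sep="\t", float_format="%.1f")
    counts = matrix.bead_count.copy()
    counts.columns = [_bead_col(b) for b in counts.columns]
    counts.index.name = "sample_id"
    counts.to_csv(counts_path, sep="\t")


def read_mfi_table(
    mfi_path, counts_path, manifest: Sequence[AntibodyRecord], samples: Sequence[SampleRecord] | None = None
) -> AssayMatrix:
    """Read paired MFI / bead-count TSVs, validated against the bead manifest.

    Rows are samples, columns ``bead_<id>``.  Columns not present in the
    manifest, missing manifest beads, and negative MFI values are rejected.
    If ``samples`` is given, the row set must match its sample ids exactly.
    """
    mfi = pd.read_csv(mfi_path, sep="\t", index_col="sample_id")
    counts = pd.read_csv(counts_path, sep="\t", index_col="sample_id")
    known = {_bead_col(r.bead_id): r.bead_id for r in manifest}
    unknown = [c for c in mfi.columns if c not in known]
    if unknown:
        raise PanelValidationError("MFI columns absent from bead manifest", unknown)
    missing = sorted(set(known) - set(mfi.columns))
    if missing:
        raise PanelValidationError("manifest beads missing from MFI table", missing)
    if samples is not None:
        want = {s.sample_id for s in samples}
        extra = sorted(set(mfi.index) - want)
        absent = sorted(want - set(mfi.index))
        if extra or absent:
            raise PanelValidationError("sample rows disagree with sample manifest", extra + absent)
    if (mfi.to_numpy(dtype=float) < 0).any():
        offenders = [
            f"{s}/{c}" for s, c in zip(*np.where(mfi.to_numpy(dtype=float) < 0))
        ]
        raise PanelValidationError("negative MFI values", offenders[:10])
    mfi.columns = [known[c] for c in mfi.columns]
    counts.columns = [known[c] for c in counts.columns]
    counts = counts.loc[mfi.index, mfi.columns].astype(int)
    return AssayMatrix(mfi.astype(float), counts)


def write_antibody_manifest(records: Sequence[AntibodyRecord], path) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)


def read_antibody_manifest(path) -> list[AntibodyRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        start = None if pd.isna(row.antigen_start) else int(row.antigen_start)
        end = None if pd.isna(row.antigen_end) else int(row.antigen_end)
        records.append(
            AntibodyRecord(
                antibody_id=str(row.antibody_id),
                bead_id=int(row.bead_id),
                target_id=str(row.target_id),
                subfamily_panel=str(row.subfamily_panel),
                antigen_start=start,
                antigen_end=end,
                source="" if pd.isna(row.source) else str(row.source),
            )
        )
    _require_unique([r.bead_id for r in records], "duplicate bead_id in manifest")
    _require_unique([r.antibody_id for r in records], "duplicate antibody_id in manifest")
    return records


def write_sample_manifest(records: Sequence[SampleRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, sep="\t", index=False)


def read_sample_manifest(path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t")
    records = [
        SampleRecord(
            sample_id=str(r.sample_id),
            construct=str(r.construct),
            bio_replicate=int(r.bio_replicate),
            tech_replicate=int(r.tech_replicate),
            panel=str(r.panel),
        )
        for r in df.itertuples(index=False)
    ]
    _require_unique([r.sample_id for r in records], "duplicate sample_id")
    return records


def write_gpcr_library(records: Sequence[GPCRRecord], fasta_path, meta_path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.gpcr_id, description="") for r in records]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    meta = pd.DataFrame(
        [
            {
                "gpcr_id": r.gpcr_id,
                "subfamily": r.subfamily,
                "n_tag": r.n_tag,
                "c_tag": r.c_tag,
                "orphan": r.orphan,
            }
            for r in records
        ]
    )
    meta.to_csv(meta_path, sep="\t", index=False)


def read_gpcr_library(fasta_path, meta_path) -> list[GPCRRecord]:
    """Join FASTA sequences with the metadata TSV, 1:1 on gpcr_id."""
    seqs = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise PanelValidationError("duplicate FASTA id", [rec.id])
        seqs[rec.id] = str(rec.seq).upper()
    meta = pd.read_csv(meta_path, sep="\t")
    meta_ids = list(meta["gpcr_id"].astype(str))
    _require_unique(meta_ids, "duplicate gpcr_id in metadata")
    only_fasta = sorted(set(seqs) - set(meta_ids))
    only_meta = sorted(set(meta_ids) - set(seqs))
    if only_fasta or only_meta:
        raise PanelValidationError(
            "FASTA and metadata ids do not match", only_fasta + only_meta
        )
    records = []
    for row in meta.itertuples(index=False):
        records.append(
            GPCRRecord(
                gpcr_id=str(row.gpcr_id),
                subfamily=str(row.subfamily),
                sequence=seqs[str(row.gpcr_id)],
                n_tag=str(row.n_tag),
                c_tag=str(row.c_tag),
                orphan=bool(row.orphan),
            )
        )
    return records


def _require_unique(items: Iterable, message: str) -> None:
    seen, dups = set(), []
    for it in items:
        if it in seen:
            dups.append(it)
        seen.add(it)
    if dups:
        raise PanelValidationError(message, dups)


# ---------------------------------------------------------------------------
# Panel validation
# ---------------------------------------------------------------------------


def validate_panel(
    manifest: Sequence[AntibodyRecord],
    samples: Sequence[SampleRecord],
    library: Sequence[GPCRRecord],
) -> ValidationReport:
    """Cross-check manifests against the construct library.

    Collects every violation instead of stopping at the first: antibody
    targets must exist in the library, non-mock sample constructs must exist,
    every panel needs at least one mock sample, bead ids and sample keys must
    be unique.
    """
    report = ValidationReport()
    lib_ids = {g.gpcr_id for g in library}

    for ab in manifest:
        if not ab.is_control and ab.target_id not in lib_ids:
            report.violations.append(
                f"antibody {ab.antibody_id} targets {ab.target_id!r} absent from library"
            )
    bead_ids = [ab.bead_id for ab in manifest]
    for b in sorted({b for b in bead_ids if bead_ids.count(b) > 1}):
        report.violations.append(f"bead_id {b} assigned more than once")

    panels_with_mock = set()
    seen_keys = set()
    for s in samples:
        if s.is_mock:
            panels_with_mock.add(s.panel)
        elif s.construct not in lib_ids:
            report.violations.append(
                f"sample {s.sample_id} expresses unknown construct {s.construct!r}"
            )
        key = (s.construct, s.bio_replicate, s.tech_replicate, s.panel)
        if key in seen_keys:
            report.violations.append(f"duplicate sample key {key}")
        seen_keys.add(key)
    for panel in sorted({s.panel for s in samples}):
        if panel not in panels_with_mock:
            report.violations.append(f"panel {panel} has no mock sample")
    return report
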