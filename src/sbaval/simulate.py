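"""Synthetic suspension-bead-array experiments with a ground-truth ledger.

The generator emulates the screen this package analyses: a library of
epitope-tagged receptor constructs expressed in four biological replicates,
solubilised and run against subfamily-specific antibody bead panels.  Each
antibody is planted as one of four selectivity classes (on-target, co-target,
off-target, no-binder), cross-reactivity is planted through two distinct
mechanisms (sequence homology via a shared mutated ancestral segment, or
sheer abundance of a dissimilar construct), and every latent variable is
recorded in a :class:`GroundTruth` ledger so downstream stages can be tested
by parameter recovery.

Signal model, per antibody bead *i* and sample *s*::

    MFI(i, s) = min(S, b + sum_g affinity(i, g) * level(g, s)) * exp(eps)

with detector saturation ``S``, assay background ``b`` and multiplicative
lognormal noise ``eps ~ N(0, sigma_n^2)``.  Construct levels are lognormal;
failed constructs are drawn from the mock (empty-vector) distribution.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    MOCK,
    SUBFAMILIES,
    AntibodyRecord,
    AssayMatrix,
    GPCRRecord,
    SampleRecord,
    write_antibody_manifest,
    write_gpcr_library,
    write_mfi_table,
    write_sample_manifest,
)

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

_DEFAULT_PANEL_SIZES = {
    "rhodopsin_alpha": 8,
    "rhodopsin_beta": 5,
    "rhodopsin_gamma": 7,
    "rhodopsin_delta": 6,
    "GSAF": 5,
    "other": 3,
}

# Per-subfamily probability that a construct fails to express, patterned on
# the observed per-subfamily expression success rates of this assay type.
_DEFAULT_FAILURE_PROBS = {
    "rhodopsin_alpha": 0.068,
    "rhodopsin_beta": 0.143,
    "rhodopsin_gamma": 0.137,
    "rhodopsin_delta": 0.261,
    "GSAF": 0.138,
    "other": 0.333,
}


@dataclass
class SimulationConfig:
    """All tunable knobs of the generator; defaults define the study design."""

    seed: int = 0
    n_gpcrs_per_subfamily: dict = field(default_factory=lambda: dict(_DEFAULT_PANEL_SIZES))
    n_abs: int = 64
    n_fzd_in_gsaf: int = 2

    # library sequences: [unique prefix | shared subfamily segment | unique suffix]
    prefix_length: int = 160
    segment_length: int = 80
    suffix_length: int = 160
    mutation_rate: float = 0.08

    # antigen length distribution (residues), truncated normal
    antigen_length_mean: float = 54.0
    antigen_length_sd: float = 26.0
    antigen_length_min: int = 20
    antigen_length_max: int = 150

    # sample layout
    n_bio_replicates: int = 4
    n_tech_replicates: int = 1
    n_mock_per_panel: int = 4

    # expression model (arbitrary abundance units, lognormal)
    mock_log_mean: float = math.log(30.0)
    expression_fold: float = 50.0
    sigma_e: float = 0.35
    failure_probs: dict = field(default_factory=lambda: dict(_DEFAULT_FAILURE_PROBS))

    # binding / detection model
    background: float = 60.0
    a_on: float = 20.0
    # tag-capture affinity kept low so tag MFI stays linear even for
    # abundance-boosted constructs (expression ratios must not compress)
    a_tag: float = 3.0
    a_cross_homology: float = 12.0
    a_cross_abundance: float = 3.0
    abundance_boost: float = 4.0
    saturation: float = 60000.0
    sigma_n: float = 0.12

    # planted class mix and cross-reactivity mechanism
    class_fractions: dict = field(
        default_factory=lambda: {"on": 0.61, "co": 0.04, "off": 0.08, "none": 0.27}
    )
    crossreact_mode: str = "mixed"  # mixed | homology | abundance

    # bead counts and coupling QC
    bead_count_floor: int = 35
    bead_count_mean: float = 100.0
    dropout_rate: float = 0.01
    coupling_failure_rate: float = 0.02
    n_coupling_runs: int = 3

    def __post_init__(self):
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        if not (self.saturation > self.background > 0):
            raise ValueError("need saturation > background > 0")
        if min(self.sigma_e, self.sigma_n) < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.crossreact_mode not in ("mixed", "homology", "abundance"):
            raise ValueError(f"unknown crossreact_mode {self.crossreact_mode!r}")

    @property
    def mu_e(self) -> float:
        """Log-mean of expressed-construct levels (mock log-mean + log fold)."""
        return self.mock_log_mean + math.log(self.expression_fold)


@dataclass
class AntibodyTruth:
    planted_class: str  # on | co | off | none
    affinities: dict  # gpcr_id -> affinity (absent = 0)
    mechanism: str | None = None  # homology | abundance, for planted cross-reactivity
    off_partner: str | None = None
    coupling_failed: bool = False


@dataclass
class GroundTruth:
    """Latent state of one simulated experiment."""

    antibodies: dict  # antibody_id -> AntibodyTruth
    sample_levels: dict  # sample_id -> tagged-protein level in that well
    failed_constructs: list
    boosted_constructs: dict  # gpcr_id -> boost factor
    segment_spans: dict  # gpcr_id -> (start, end) of the shared segment, 1-based

    def to_json(self) -> str:
        payload = {
            "antibodies": {k: dataclasses.asdict(v) for k, v in self.antibodies.items()},
            "sample_levels": self.sample_levels,
            "failed_constructs": self.failed_constructs,
            "boosted_constructs": self.boosted_constructs,
            "segment_spans": {k: list(v) for k, v in self.segment_spans.items()},
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class Dataset:
    """One panel-complete synthetic experiment."""

    config: SimulationConfig
    library: list
    antibodies: list
    samples: list
    matrix: AssayMatrix
    coupling: AssayMatrix
    truth: GroundTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gpcr_library(self.library, outdir / "library.fasta", outdir / "library_meta.tsv")
        write_antibody_manifest(self.antibodies, outdir / "antibodies.tsv")
        write_sample_manifest(self.samples, outdir / "samples.tsv")
        write_mfi_table(self.matrix, outdir / "mfi.tsv", outdir / "bead_counts.tsv")
        write_mfi_table(self.coupling, outdir / "coupling_mfi.tsv", outdir / "coupling_counts.tsv")
        (outdir / "ground_truth.json").write_text(self.truth.to_json())


# ---------------------------------------------------------------------------
# Library
# ---------------------------------------------------------------------------


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(_AA, size=n))


def _mutate(rng, seq: str, rate: float) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = _AA[_AA != out[i]]
        out[i] = rng.choice(choices)
    return "".join(out)


def simulate_library(config: SimulationConfig, rng=None) -> list:
    """Random construct library with homology planted within subfamilies.

    Members of one subfamily share a common ancestral segment, independently
    mutated per member at ``config.mutation_rate``; segments of different
    subfamilies are independent, so cross-subfamily homology is absent by
    construction.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    library = []
    for fam in SUBFAMILIES:
        n = config.n_gpcrs_per_subfamily.get(fam, 0)
        if n == 0:
            continue
        ancestor = _random_seq(rng, config.segment_length)
        for i in range(n):
            gid = f"{fam.upper()}_{i + 1:02d}"
            seq = (
                _random_seq(rng, config.prefix_length)
                + _mutate(rng, ancestor, config.mutation_rate)
                + _random_seq(rng, config.suffix_length)
            )
            is_fzd = fam == "GSAF" and i < config.n_fzd_in_gsaf
            library.append(
                GPCRRecord(
                    gpcr_id=gid,
                    subfamily=fam,
                    sequence=seq,
                    n_tag="HA" if is_fzd else "FLAG",
                    orphan=bool(rng.random() < 0.2),
                )
            )
    return library


def segment_span(config: SimulationConfig) -> tuple:
    """1-based inclusive span of the shared segment on every construct."""
    return (config.prefix_length + 1, config.prefix_length + config.segment_length)


def make_samples(config: SimulationConfig, library) -> list:
    """Deterministic sample layout: replicates per construct plus mocks."""
    samples = []
    for g in library:
        for b in range(1, config.n_bio_replicates + 1):
            for t in range(1, config.n_tech_replicates + 1):
                samples.append(
                    SampleRecord(f"{g.gpcr_id}.b{b}t{t}", g.gpcr_id, b, t, g.subfamily)
                )
    panels = sorted({g.subfamily for g in library}, key=SUBFAMILIES.index)
    for fam in panels:
        for b in range(1, config.n_mock_per_panel + 1):
            samples.append(SampleRecord(f"MOCK.{fam}.b{b}", MOCK, b, 1, fam))
    return samples


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def _draw_expression(config, library, samples, rng, forced_expressed=(), boosted=None):
    """Per-well tagged-protein levels; returns (levels, failed_constructs).

    Levels are lognormal: expressed constructs around
    ``exp(mu_e)``, failed constructs and mock wells around ``exp(mock_log_mean)``
    (the residual nonspecific capture level), making failures indistinguishable
    from mock in expectation.
    """
    boosted = boosted or {}
    failed = []
    for g in library:
        p = config.failure_probs.get(g.subfamily, 0.0)
        if g.gpcr_id not in forced_expressed and rng.random() < p:
            failed.append(g.gpcr_id)
    failed_set = set(failed)
    levels = {}
    for s in samples:
        if s.is_mock or s.construct in failed_set:
            mu = config.mock_log_mean
        else:
            mu = config.mu_e + math.log(boosted.get(s.construct, 1.0))
        levels[(s.construct, s.sample_id)] = float(
            math.exp(rng.normal(mu, config.sigma_e))
        )
    return levels, failed


def simulate_expression(config: SimulationConfig, library, samples=None, rng=None):
    """Draw per-well construct levels; map of (gpcr_id, sample_id) -> level."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    samples = make_samples(config, library) if samples is None else samples
    levels, _ = _draw_expression(config, library, samples, rng)
    return levels


# ---------------------------------------------------------------------------
# Panel design: classes, antigens, affinities
# ---------------------------------------------------------------------------


def _class_counts(fractions: dict, n: int) -> dict:
    """Largest-remainder apportionment of n antibodies over the class mix."""
    order = ["on", "co", "off", "none"]
    raw = {c: fractions.get(c, 0.0) * n for c in order}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    rem = n - sum(counts.values())
    for c in sorted(order, key=lambda c: raw[c] - counts[c], reverse=True)[:rem]:
        counts[c] += 1
    return counts


def _draw_antigen_span(config, rng, region_start, region_end, max_len=None):
    """1-based inclusive span with truncated-normal length inside a region."""
    region_len = region_end - region_start + 1
    hi = min(config.antigen_length_max, region_len)
    if max_len is not None:
        hi = min(hi, max_len)
    lo = min(config.antigen_length_min, hi)
    while True:
        length = int(round(rng.normal(config.antigen_length_mean, config.antigen_length_sd)))
        if lo <= length <= hi:
            break
    start = int(rng.integers(region_start, region_end - length + 2))
    return start, start + length - 1


def _design_panel(config: SimulationConfig, library, rng):
    """Assign targets, planted classes, antigen spans and affinities."""
    by_fam = {}
    for g in library:
        by_fam.setdefault(g.subfamily, []).append(g)

    # round-robin target assignment so most targets get >=2 antibodies
    targets = [library[i % len(library)] for i in range(config.n_abs)]
    counts = _class_counts(config.class_fractions, config.n_abs)
    classes = (
        ["on"] * counts["on"] + ["co"] * counts["co"] + ["off"] * counts["off"] + ["none"] * counts["none"]
    )
    classes = [classes[i] for i in rng.permutation(config.n_abs)]

    seg_start, seg_end = segment_span(config)
    # constructs serving as the on-target of a planted cross-reactive antibody
    # must not double as (boosted) off-target partners, or expression ratios
    # would be confounded
    co_off_targets = {
        t.gpcr_id for t, c in zip(targets, classes) if c in ("co", "off")
    }
    antibodies, truths = [], {}
    cross_idx = 0
    for i, (target, cls) in enumerate(zip(targets, classes)):
        ab_id = f"AB{i + 1:04d}"
        mechanism = None
        partner = None
        affinities = {}
        if cls in ("co", "off"):
            if config.crossreact_mode == "mixed":
                mechanism = "homology" if cross_idx % 2 == 0 else "abundance"
            else:
                mechanism = config.crossreact_mode
            cross_idx += 1
            others = [
                g
                for g in by_fam[target.subfamily]
                if g.gpcr_id != target.gpcr_id and g.gpcr_id not in co_off_targets
            ]
            if not others:
                others = [g for g in by_fam[target.subfamily] if g.gpcr_id != target.gpcr_id]
            partner = others[int(rng.integers(len(others)))].gpcr_id
        if mechanism == "homology":
            # antigen inside the shared segment: the partner's homologous
            # segment is what the antibody cross-reacts with
            span = _draw_antigen_span(config, rng, seg_start, seg_end)
            affinities[partner] = config.a_cross_homology
        else:
            region = (1, config.prefix_length) if rng.random() < 0.5 else (
                seg_end + 1,
                len(target.sequence),
            )
            span = _draw_antigen_span(config, rng, region[0], region[1])
            if mechanism == "abundance":
                affinities[partner] = config.a_cross_abundance
        if cls in ("on", "co"):
            affinities[target.gpcr_id] = config.a_on
        if cls == "none":
            affinities = {}
        antibodies.append(
            AntibodyRecord(
                antibody_id=ab_id,
                bead_id=101 + i,
                target_id=target.gpcr_id,
                subfamily_panel=target.subfamily,
                antigen_start=span[0],
                antigen_end=span[1],
                source="synthetic",
            )
        )
        truths[ab_id] = AntibodyTruth(
            planted_class=cls,
            affinities=affinities,
            mechanism=mechanism,
            off_partner=partner,
        )
    return antibodies, truths


def _control_beads(config, library, first_bead_id):
    """Per-panel tag-capture and coupling-control beads."""
    panels = sorted({g.subfamily for g in library}, key=SUBFAMILIES.index)
    beads = []
    bead_id = first_bead_id
    for fam in panels:
        for role in ("anti-FLAG", "anti-HA", "anti-1D4", "coupling-control"):
            beads.append(
                AntibodyRecord(
                    antibody_id=f"CTRL.{fam}.{role}",
                    bead_id=bead_id,
                    target_id=role,
                    subfamily_panel=fam,
                )
            )
            bead_id += 1
    return beads


# ---------------------------------------------------------------------------
# MFI matrix
# ---------------------------------------------------------------------------


def simulate_mfi(config: SimulationConfig, truth: GroundTruth, samples, antibodies, library, rng=None) -> AssayMatrix:
    """Linear-to-saturation signal with multiplicative lognormal noise."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lib = {g.gpcr_id: g for g in library}
    bead_ids = [ab.bead_id for ab in antibodies]
    n_s, n_b = len(samples), len(antibodies)
    base = np.full((n_s, n_b), config.background, dtype=float)

    for j, ab in enumerate(antibodies):
        abt = truth.antibodies.get(ab.antibody_id)
        for i, s in enumerate(samples):
            level = truth.sample_levels[s.sample_id]
            if ab.is_control:
                if ab.target_id == "coupling-control":
                    continue
                if s.is_mock:
                    base[i, j] += config.a_tag * level  # nonspecific residual capture
                elif ab.target_id == "anti-1D4" or (
                    ab.target_id == f"anti-{lib[s.construct].n_tag}"
                ):
                    base[i, j] += config.a_tag * level
            elif not s.is_mock and abt is not None:
                aff = abt.affinities.get(s.construct, 0.0)
                if aff:
                    base[i, j] += aff * level
    signal = np.minimum(config.saturation, base)
    if config.sigma_n > 0:
        signal = signal * np.exp(rng.normal(0.0, config.sigma_n, size=signal.shape))

    counts = config.bead_count_floor + rng.poisson(
        max(config.bead_count_mean - config.bead_count_floor, 0.0), size=signal.shape
    )
    drop = rng.random(size=signal.shape) < config.dropout_rate
    counts = np.where(drop, rng.integers(0, 32, size=signal.shape), counts)

    index = pd.Index([s.sample_id for s in samples], name="sample_id")
    mfi = pd.DataFrame(signal, index=index, columns=bead_ids)
    bead_count = pd.DataFrame(counts.astype(int), index=index, columns=bead_ids)
    return AssayMatrix(mfi, bead_count)


def _simulate_coupling(config, antibodies, truth, rng) -> AssayMatrix:
    """Dedicated anti-rabbit-detection coupling-efficiency runs."""
    bead_ids = [ab.bead_id for ab in antibodies]
    n_runs = config.n_coupling_runs
    signal = np.empty((n_runs, len(antibodies)))
    for j, ab in enumerate(antibodies):
        failed = (
            not ab.is_control
            and rng.random() < config.coupling_failure_rate
        )
        if not ab.is_control:
            truth.antibodies[ab.antibody_id].coupling_failed = failed
        mu = math.log(100.0) if failed else math.log(10000.0)
        signal[:, j] = np.exp(rng.normal(mu, 0.2, size=n_runs))
    index = pd.Index([f"coupling_{i + 1}" for i in range(n_runs)], name="sample_id")
    counts = pd.DataFrame(
        np.full_like(signal, 100, dtype=int), index=index, columns=bead_ids
    )
    return AssayMatrix(pd.DataFrame(signal, index=index, columns=bead_ids), counts)


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------


def generate_dataset(config: SimulationConfig | None = None, outdir=None) -> Dataset:
    """One call yields a panel-complete dataset that passes validation.

    Deterministic given ``config.seed``; when ``outdir`` is given, all
    standard files (TSV manifests and matrices, FASTA library, JSON truth
    ledger) are written there.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    library = simulate_library(config, rng)
    samples = make_samples(config, library)
    ab_records, ab_truths = _design_panel(config, library, rng)

    # cross-reactivity partners (and the targets of planted co/off antibodies)
    # must actually express for the planted event to be observable
    boosted = {}
    forced = set()
    for rec in ab_records:
        abt = ab_truths[rec.antibody_id]
        if abt.mechanism == "abundance":
            boosted[abt.off_partner] = config.abundance_boost
        if abt.planted_class in ("co", "off"):
            forced.add(abt.off_partner)
            forced.add(rec.target_id)

    levels, failed = _draw_expression(
        config, library, samples, rng, forced_expressed=forced, boosted=boosted
    )
    seg = segment_span(config)
    truth = GroundTruth(
        antibodies=ab_truths,
        sample_levels={s.sample_id: levels[(s.construct, s.sample_id)] for s in samples},
        failed_constructs=failed,
        boosted_constructs=boosted,
        segment_spans={g.gpcr_id: seg for g in library},
    )

    controls = _control_beads(config, library, first_bead_id=101 + config.n_abs + 100)
    all_beads = ab_records + controls
    matrix = simulate_mfi(config, truth, samples, all_beads, library, rng)
    coupling = _simulate_coupling(config, all_beads, truth, rng)

    dataset = Dataset(
        config=config,
        library=library,
        antibodies=all_beads,
        samples=samples,
        matrix=matrix,
        coupling=coupling,
        truth=truth,
    )
    if outdir is not None:
        dataset.write(outdir)
    return dataset


# ---------------------------------------------------------------------------
# Synthetic antigen structures (for the structural-feature analysis)
# ---------------------------------------------------------------------------

_BOND = {"n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231}
_ANGLE = {"n_ca_c": 111.2, "ca_c_n": 116.2, "c_n_ca": 121.7, "ca_c_o": 120.5}


def _place_atom(a, b, c, r, theta_deg, chi_deg):
    """Internal-to-Cartesian (NeRF): place D given A-B-C, bond r, angle theta
    at C, and dihedral chi about B-C."""
    theta = math.radians(theta_deg)
    # +180: with n = ab x bc the raw construction yields the supplementary
    # torsion; shifting chi makes the argument equal the measured dihedral
    chi = math.radians(chi_deg + 180.0)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = -bc * math.cos(theta) + m * math.sin(theta) * math.cos(chi) + n * math.sin(theta) * math.sin(chi)
    return c + r * d


def build_peptide(phis, psis, res_names=None, plddt=None):
    """Ideal-geometry poly-peptide backbone (N, CA, C, O) from phi/psi lists.

    ``phis[0]`` is unused (no preceding carbonyl); the last psi only places
    the terminal carbonyl oxygen.  Per-residue ``plddt`` values are written
    into the B-factor slot of every atom of the residue.
    """
    from .structure import StructureModel

    n_res = len(phis)
    if len(psis) != n_res:
        raise ValueError("phis and psis must have equal length")
    res_names = ["ALA"] * n_res if res_names is None else list(res_names)
    plddt = [math.nan] * n_res if plddt is None else list(plddt)

    N = [np.array([0.0, 0.0, 0.0])]
    theta0 = math.radians(_ANGLE["n_ca_c"])
    CA = [np.array([_BOND["n_ca"], 0.0, 0.0])]
    C = [CA[0] + _BOND["ca_c"] * np.array([-math.cos(theta0), math.sin(theta0), 0.0])]
    for i in range(1, n_res):
        N.append(_place_atom(N[i - 1], CA[i - 1], C[i - 1], _BOND["c_n"], _ANGLE["ca_c_n"], psis[i - 1]))
        CA.append(_place_atom(CA[i - 1], C[i - 1], N[i], _BOND["n_ca"], _ANGLE["c_n_ca"], 180.0))
        C.append(_place_atom(C[i - 1], N[i], CA[i], _BOND["ca_c"], _ANGLE["n_ca_c"], phis[i]))
    O = []
    for i in range(n_res):
        psi_o = psis[i] if i < n_res - 1 else 180.0
        O.append(_place_atom(N[i], CA[i], C[i], _BOND["c_o"], _ANGLE["ca_c_o"], psi_o + 180.0))

    coords, names, rids, rnames, elements, bfac = [], [], [], [], [], []
    for i in range(n_res):
        for name, xyz, elem in (("N", N[i], "N"), ("CA", CA[i], "C"), ("C", C[i], "C"), ("O", O[i], "O")):
            coords.append(xyz)
            names.append(name)
            rids.append(i + 1)
            rnames.append(res_names[i])
            elements.append(elem)
            bfac.append(plddt[i])
    return StructureModel(
        coords=np.array(coords),
        atom_names=np.array(names),
        res_ids=np.array(rids, dtype=int),
        res_names=np.array(rnames),
        elements=np.array(elements),
        b_factors=np.array(bfac, dtype=float),
    )


def _with_occlusion_cage(model, offset: float = 4.2):
    """Surround every backbone atom with dummy carbons so the chain is buried."""
    from .structure import StructureModel

    shifts = offset * np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float
    )
    cage = (model.coords[:, None, :] + shifts[None, :, :]).reshape(-1, 3)
    n_cage = len(cage)
    return StructureModel(
        coords=np.vstack([model.coords, cage]),
        atom_names=np.concatenate([model.atom_names, np.full(n_cage, "X")]),
        res_ids=np.concatenate([model.res_ids, np.full(n_cage, 9999, dtype=int)]),
        res_names=np.concatenate([model.res_names, np.full(n_cage, "UNK")]),
        elements=np.concatenate([model.elements, np.full(n_cage, "C")]),
        b_factors=np.concatenate([model.b_factors, np.full(n_cage, math.nan)]),
    )


def simulate_antigen_structures(n_per_class: int = 50, max_length: int = 45, seed: int = 0):
    """Planted exposed/disordered vs buried/ordered antigens.

    Returns (model, antigen_span, class_label) triples: 'on_target' antigens
    are long, coil-like, surface-exposed chains with low per-residue
    confidence; 'no_target' antigens are shorter ideal helices buried inside
    an occluding atom cage with high confidence.  This emulates the
    structural contrast between immunogenic and failed antigens; it is a
    synthetic stand-in for predicted-structure models, not a download.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_per_class):
        length = int(np.clip(round(rng.normal(54.0, 26.0)), 20, max_length))
        phis = rng.uniform(-100.0, -50.0, size=length)
        psis = rng.uniform(10.0, 60.0, size=length)
        plddt = np.clip(rng.normal(45.0, 8.0, size=length), 0.0, 100.0)
        model = build_peptide(phis, psis, plddt=plddt)
        out.append((model, (1, length), "on_target"))
    for _ in range(n_per_class):
        length = int(np.clip(round(rng.normal(37.0, 19.0)), 15, max_length))
        phis = rng.normal(-57.0, 3.0, size=length)
        psis = rng.normal(-47.0, 3.0, size=length)
        plddt = np.clip(rng.normal(88.0, 5.0, size=length), 0.0, 100.0)
        model = _with_occlusion_cage(build_peptide(phis, psis, plddt=plddt))
        out.append((model, (1, length), "no_target"))
    return out
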