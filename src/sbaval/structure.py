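"""Antigen feature extraction from predicted full-length structure models.

Per residue, three features drive the group comparisons between antibody
selectivity classes: the model confidence (pLDDT, read from the B-factor
field of predicted-structure files; low values indicate disorder), the
relative solvent-accessible surface area (Shrake-Rupley SASA divided by the
residue-type maximum), and a three-state secondary-structure class assigned
from backbone dihedrals (helix / sheet / coil).  Features are averaged over
each antibody's antigen span and compared between classes with
Kruskal-Wallis / rank-sum tests (antigen length) and independent two-sample
t tests (structural metrics).

The dihedral-based secondary-structure assignment deliberately replaces
hydrogen-bond (DSSP-style) logic: only three-state fractions feed the
statistics, and the interface also accepts precomputed per-residue strings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

#: Van der Waals radii (Angstrom) by element.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
DEFAULT_RADIUS = 1.70
PROBE_RADIUS = 1.4

#: Theoretical maximum SASA per residue type (Angstrom^2), Tien et al. 2013.
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

# Ramachandran windows (degrees) and minimum run lengths for the three-state
# assignment; the ideal alpha helix (-57, -47) and extended strand
# (-139, 135) fall comfortably inside.
HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
SHEET_PHI = (-170.0, -70.0)
SHEET_PSI = (90.0, 180.0)
MIN_HELIX_RUN = 4
MIN_SHEET_RUN = 3


@dataclass
class StructureModel:
    """Single-chain atomic model with per-atom confidence values."""

    coords: np.ndarray  # (n_atoms, 3)
    atom_names: np.ndarray
    res_ids: np.ndarray  # residue index per atom, 1-based
    res_names: np.ndarray
    elements: np.ndarray
    b_factors: np.ndarray  # NaN when the source had none

    @property
    def residue_ids(self) -> np.ndarray:
        seen = dict.fromkeys(int(r) for r in self.res_ids)
        return np.array(list(seen), dtype=int)

    def residue_plddt(self) -> dict:
        """Per-residue confidence: the CA B-factor (mean over atoms if no CA)."""
        out = {}
        for rid in self.residue_ids:
            m = self.res_ids == rid
            ca = m & (self.atom_names == "CA")
            vals = self.b_factors[ca] if ca.any() else self.b_factors[m]
            out[int(rid)] = float(np.mean(vals)) if vals.size else math.nan
        return out

    def backbone(self, rid: int) -> dict:
        """N/CA/C coordinates of one residue (missing atoms absent)."""
        m = self.res_ids == rid
        out = {}
        for name in ("N", "CA", "C"):
            sel = m & (self.atom_names == name)
            if sel.any():
                out[name] = self.coords[sel][0]
        return out


def _radii_for(elements) -> np.ndarray:
    return np.array([VDW_RADII.get(str(e).upper(), DEFAULT_RADIUS) for e in elements])


# ---------------------------------------------------------------------------
# File reading / writing (PDB and mmCIF via biotite)
# ---------------------------------------------------------------------------


def _from_atom_array(atoms) -> StructureModel:
    try:
        b = np.asarray(atoms.b_factor, dtype=float)
    except AttributeError:
        b = np.full(atoms.array_length(), math.nan)
    return StructureModel(
        coords=np.asarray(atoms.coord, dtype=float),
        atom_names=np.asarray(atoms.atom_name),
        res_ids=np.asarray(atoms.res_id, dtype=int),
        res_names=np.asarray(atoms.res_name),
        elements=np.asarray(atoms.element),
        b_factors=b,
    )


def read_structure_model(path) -> StructureModel:
    """Read a single-chain PDB or mmCIF model; pLDDT from the B-factor field.

    Multi-model files use the first model with a warning; more than one chain
    is an error; absent B-factors yield NaN confidence.
    """
    import biotite.structure.io.pdb as pdbio
    import biotite.structure.io.pdbx as pdbxio

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        f = pdbio.PDBFile.read(str(path))
        try:
            stack = f.get_structure(extra_fields=["b_factor"])
        except Exception:
            stack = f.get_structure()
    elif suffix in (".cif", ".mmcif", ".pdbx"):
        f = pdbxio.CIFFile.read(str(path))
        try:
            stack = pdbxio.get_structure(f, extra_fields=["b_factor"])
        except Exception:
            stack = pdbxio.get_structure(f)
    else:
        raise ValueError(f"unrecognised structure format: {path.name}")
    n_models = stack.stack_depth()
    if n_models > 1:
        warnings.warn(f"{path.name} holds {n_models} models; using the first")
    atoms = stack[0]
    chains = np.unique(atoms.chain_id)
    if len(chains) > 1:
        raise ValueError(f"{path.name} has {len(chains)} chains; single-chain models only")
    return _from_atom_array(atoms)


def _to_atom_array(model: StructureModel):
    import biotite.structure as struc

    n = len(model.coords)
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(model.coords, dtype=np.float32)
    atoms.atom_name = model.atom_names
    atoms.res_id = model.res_ids
    atoms.res_name = model.res_names
    atoms.element = model.elements
    atoms.chain_id = np.full(n, "A")
    atoms.hetero = np.full(n, False)
    atoms.set_annotation("b_factor", np.nan_to_num(model.b_factors))
    return atoms


def write_structure_model(model: StructureModel, path) -> None:
    """Write a model as PDB or mmCIF (chosen by extension); B-factor = pLDDT."""
    import biotite.structure.io.pdb as pdbio
    import biotite.structure.io.pdbx as pdbxio

    path = Path(path)
    atoms = _to_atom_array(model)
    if path.suffix.lower() in (".pdb", ".ent"):
        f = pdbio.PDBFile()
        f.set_structure(atoms)
        f.write(str(path))
    else:
        f = pdbxio.CIFFile()
        pdbxio.set_structure(f, atoms)
        f.write(str(path))


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------


def sphere_points(n: int) -> np.ndarray:
    """n near-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(coords, radii, probe: float = PROBE_RADIUS, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area by sphere-point sampling.

    Each atom's solvent sphere (radius + probe) is sampled at ``n_points``
    near-uniform points; a point is accessible when inside no neighbouring
    solvent sphere.  Area = accessible fraction x sphere area.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    expanded = radii + probe
    pts = sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = expanded.max()
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        r = expanded[i]
        cand = tree.query_ball_point(coords[i], r + max_r)
        nb = [j for j in cand if j != i]
        if nb:
            d = np.linalg.norm(coords[nb] - coords[i], axis=1)
            nb = [j for j, dj in zip(nb, d) if dj < r + expanded[j]]
        if not nb:
            areas[i] = 4.0 * math.pi * r * r
            continue
        test = coords[i] + pts * r
        d2 = ((test[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
        buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
        areas[i] = 4.0 * math.pi * r * r * float((~buried).mean())
    return areas


def residue_sasa(model: StructureModel, probe: float = PROBE_RADIUS, n_points: int = 960) -> dict:
    """Per-residue sums of atomic SASA."""
    atom_areas = shrake_rupley_sasa(model.coords, _radii_for(model.elements), probe, n_points)
    out = {}
    for rid in model.residue_ids:
        out[int(rid)] = float(atom_areas[model.res_ids == rid].sum())
    return out


def relative_sasa(abs_sasa, residue_types) -> np.ndarray:
    """Absolute SASA divided by the residue-type maximum, clipped to [0, 1]."""
    abs_sasa = np.asarray(abs_sasa, dtype=float)
    maxima = np.array([MAX_SASA.get(str(r).upper(), math.nan) for r in residue_types])
    rel = abs_sasa / maxima
    over = rel > 1.0
    if np.any(over[np.isfinite(rel)]):
        warnings.warn(f"{int(np.nansum(over))} residue(s) exceeded the tabulated "
                      "maximum SASA; clipped to 1.0")
    return np.clip(rel, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Secondary structure from backbone dihedrals
# ---------------------------------------------------------------------------


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def backbone_dihedrals(model: StructureModel) -> pd.DataFrame:
    """Phi/psi per residue (NaN at chain termini or missing backbone atoms)."""
    rids = list(model.residue_ids)
    bb = {rid: model.backbone(rid) for rid in rids}
    rows = []
    for idx, rid in enumerate(rids):
        cur = bb[rid]
        phi = psi = math.nan
        if idx > 0 and all(k in cur for k in ("N", "CA", "C")):
            prev = bb[rids[idx - 1]]
            if "C" in prev:
                phi = _dihedral(prev["C"], cur["N"], cur["CA"], cur["C"])
        if idx < len(rids) - 1 and all(k in cur for k in ("N", "CA", "C")):
            nxt = bb[rids[idx + 1]]
            if "N" in nxt:
                psi = _dihedral(cur["N"], cur["CA"], cur["C"], nxt["N"])
        rows.append({"res_id": rid, "phi": phi, "psi": psi})
    return pd.DataFrame(rows)


def _in_window(val: float, lo_hi) -> bool:
    return not math.isnan(val) and lo_hi[0] < val < lo_hi[1]


def assign_secondary_structure(model: StructureModel) -> dict:
    """Three-state assignment {res_id: 'helix'|'sheet'|'coil'}.

    A residue is a helix/sheet candidate when both dihedrals fall in the
    corresponding Ramachandran window; candidates only count when part of a
    run of at least 4 (helix) or 3 (sheet) consecutive residues.
    """
    dihedrals = backbone_dihedrals(model)
    rids = dihedrals["res_id"].to_numpy()
    helix_cand = np.array(
        [
            _in_window(p, HELIX_PHI) and _in_window(s, HELIX_PSI)
            for p, s in zip(dihedrals["phi"], dihedrals["psi"])
        ]
    )
    sheet_cand = np.array(
        [
            _in_window(p, SHEET_PHI) and _in_window(s, SHEET_PSI)
            for p, s in zip(dihedrals["phi"], dihedrals["psi"])
        ]
    )
    ss = np.full(len(rids), "coil", dtype=object)
    for cand, label, min_run in (
        (helix_cand, "helix", MIN_HELIX_RUN),
        (sheet_cand, "sheet", MIN_SHEET_RUN),
    ):
        i = 0
        while i < len(cand):
            if cand[i]:
                j = i
                while j < len(cand) and cand[j]:
                    j += 1
                if j - i >= min_run:
                    ss[i:j] = label
                i = j
            else:
                i += 1
    return {int(r): s for r, s in zip(rids, ss)}


# ---------------------------------------------------------------------------
# Antigen profiles and group statistics
# ---------------------------------------------------------------------------


def extract_residue_annotations(
    model: StructureModel,
    probe: float = PROBE_RADIUS,
    n_points: int = 960,
    ss: dict | None = None,
) -> pd.DataFrame:
    """Per-residue feature table: pLDDT, absolute/relative SASA, SS class.

    ``ss`` may supply a precomputed {res_id: class} map (e.g. from an
    external DSSP run) to bypass the dihedral-based assignment.
    """
    plddt = model.residue_plddt()
    sasa = residue_sasa(model, probe, n_points)
    ss = assign_secondary_structure(model) if ss is None else ss
    rids = model.residue_ids
    res_names = {int(r): str(model.res_names[model.res_ids == r][0]) for r in rids}
    df = pd.DataFrame(
        {
            "res_id": rids,
            "res_name": [res_names[int(r)] for r in rids],
            "plddt": [plddt[int(r)] for r in rids],
            "abs_sasa": [sasa[int(r)] for r in rids],
            "ss": [ss.get(int(r), "coil") for r in rids],
        }
    )
    df["rel_sasa"] = relative_sasa(df["abs_sasa"].to_numpy(), df["res_name"].to_numpy())
    return df


@dataclass
class AntigenProfile:
    antibody_id: str
    length: int
    mean_plddt: float
    mean_rel_sasa: float
    ss_fractions: dict  # {helix, sheet, coil}, sums to 1
    complete: bool = True


def antigen_profile(annotations: pd.DataFrame, antigen_span, antibody_id: str = "") -> AntigenProfile:
    """Means and SS fractions over the antigen span (1-based inclusive).

    Spans extending beyond the model's resolved residues are flagged
    incomplete (and should be excluded from group statistics).
    """
    start, end = antigen_span
    want = set(range(start, end + 1))
    sub = annotations[annotations["res_id"].isin(want)]
    complete = len(sub) == len(want)
    if not complete:
        warnings.warn(
            f"antigen span {start}-{end} of {antibody_id or 'antibody'} covers "
            f"{len(sub)}/{len(want)} resolved residues; profile incomplete"
        )
    n = max(len(sub), 1)
    fractions = {
        s: float((sub["ss"] == s).sum()) / n for s in ("helix", "sheet", "coil")
    }
    return AntigenProfile(
        antibody_id=antibody_id,
        length=end - start + 1,
        mean_plddt=float(sub["plddt"].mean()) if len(sub) else math.nan,
        mean_rel_sasa=float(sub["rel_sasa"].mean()) if len(sub) else math.nan,
        ss_fractions=fractions,
        complete=complete,
    )


def profiles_frame(profiles, classes: dict) -> pd.DataFrame:
    """Tabulate complete profiles with their selectivity class labels."""
    rows = []
    for p in profiles:
        if not p.complete:
            continue
        rows.append(
            {
                "antibody_id": p.antibody_id,
                "class": classes.get(p.antibody_id, "unknown"),
                "length": p.length,
                "mean_plddt": p.mean_plddt,
                "mean_rel_sasa": p.mean_rel_sasa,
                "helix": p.ss_fractions["helix"],
                "sheet": p.ss_fractions["sheet"],
                "coil": p.ss_fractions["coil"],
            }
        )
    return pd.DataFrame(rows)


def compare_groups(frame: pd.DataFrame, group_col: str = "class") -> pd.DataFrame:
    """Group statistics between selectivity classes.

    Antigen length: Kruskal-Wallis omnibus plus pairwise two-sided rank-sum
    (Mann-Whitney) tests.  Structural metrics (pLDDT, relative SASA, SS
    fractions): pairwise independent two-sample t tests.  Output rows carry
    the statistic, p-value and per-group mean +/- sd with n.
    """
    groups = sorted(frame[group_col].unique())
    by_group = {g: frame[frame[group_col] == g] for g in groups}
    rows = []

    def _desc(vals):
        v = np.asarray(vals, dtype=float)
        return float(np.mean(v)), float(np.std(v, ddof=1)) if v.size > 1 else math.nan, int(v.size)

    length_groups = [by_group[g]["length"].to_numpy(dtype=float) for g in groups]
    if len(groups) >= 2:
        kw = stats.kruskal(*length_groups)
        rows.append(
            {
                "metric": "length", "comparison": "omnibus", "test": "kruskal",
                "statistic": float(kw.statistic), "p_value": float(kw.pvalue),
                "group_a": "all", "mean_a": math.nan, "sd_a": math.nan, "n_a": int(len(frame)),
                "group_b": "", "mean_b": math.nan, "sd_b": math.nan, "n_b": 0,
            }
        )
    for metric, test in [
        ("length", "ranksum"),
        ("mean_plddt", "ttest"),
        ("mean_rel_sasa", "ttest"),
        ("helix", "ttest"),
        ("sheet", "ttest"),
        ("coil", "ttest"),
    ]:
        for i, a in enumerate(groups):
            for b in groups[i + 1 :]:
                va = by_group[a][metric].to_numpy(dtype=float)
                vb = by_group[b][metric].to_numpy(dtype=float)
                va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
                if test == "ranksum":
                    res = stats.mannwhitneyu(va, vb, alternative="two-sided")
                else:
                    res = stats.ttest_ind(va, vb)
                ma, sa, na = _desc(va)
                mb, sb, nb = _desc(vb)
                rows.append(
                    {
                        "metric": metric, "comparison": f"{a} vs {b}", "test": test,
                        "statistic": float(res.statistic), "p_value": float(res.pvalue),
                        "group_a": a, "mean_a": ma, "sd_a": sa, "n_a": na,
                        "group_b": b, "mean_b": mb, "sd_b": sb, "n_b": nb,
                    }
                )
    return pd.DataFrame(rows)
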