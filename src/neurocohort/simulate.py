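"""Seeded synthetic cohort generator with known ground-truth effects.

Emulates the structure of a multi-site pediatric imaging/genetics study:
ages 3-21 years, gender, scanner device identifiers from multiple
acquisition sites, ordinal household income and parental education,
Dirichlet ancestry proportion factors summing to 1, intracranial
volume, a total cortical surface area measure driven by a smooth
unimodal age curve with a gender-specific peak (boys peak earlier and
decline faster), region-of-interest and vertex-wise area-expansion
measures on icosphere hemisphere meshes, and Hardy-Weinberg genotypes
in a PLINK trio with a gene location table.

Every generated artifact is deterministic given the seed, and a
``truth.json`` sidecar records the generating parameters plus the
realized effect targets that parameter-recovery tests assert against.
The generator targets the *structure* of such a study, not any real
study's effect sizes or distributions.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .snp import GenotypeMatrix, SNPRecord, write_plink
from .surface import SurfaceMesh, VertexMeasureMatrix, write_ply

__all__ = [
    "SimulationParams",
    "CohortFixture",
    "generate_cohort",
    "generate_genotypes",
    "generate_null_pvalue_sets",
    "age_curve",
]

ROI_NAMES = (
    "precentral",
    "postcentral",
    "superiorfrontal",
    "superiorparietal",
    "lateraloccipital",
    "middletemporal",
    "medialorbitofrontal",
    "precuneus",
)

GENE_TABLE = [
    # name, chromosome, start_bp, end_bp
    ("SHH", "7", 155_592_735, 155_601_766),
    ("STON2", "14", 81_234_000, 81_288_000),
    ("HOXA1", "7", 27_092_993, 27_096_000),
    ("HOXA2", "7", 27_100_000, 27_102_000),
    ("FOXP2", "7", 114_086_327, 114_693_772),
    ("BDNF", "11", 27_654_893, 27_722_058),
    ("COMT", "22", 19_941_772, 19_969_975),
]


@dataclasses.dataclass
class SimulationParams:
    """Generating conditions for the synthetic study."""

    n_subjects: int = 800
    seed: int = 42
    age_range: tuple[float, float] = (3.0, 21.0)
    gender_balance: float = 0.5
    n_sites: int = 10
    k_ancestry: int = 5
    dirichlet_alpha: float = 0.5
    ses_levels: int = 5
    ses_missing_rate: float = 0.05
    # total cortical area model (mm^2)
    area_baseline: float = 170_000.0
    area_amplitude: float = 15_000.0
    curve_shape: float = 4.0
    peak_age_male: float = 9.5
    peak_age_female: float = 10.5
    gender_beta: float = 500.0          # additive male-female offset
    device_offset_sd: float = 250.0
    income_slope: float = 800.0         # per ordinal income level
    education_slope: float = 300.0      # per ordinal education level
    ancestry_slopes: tuple[float, ...] = (2000.0, -1500.0, 1000.0, 0.0, -1000.0)
    icv_mean: float = 1.45e6
    icv_sd: float = 1.2e5
    icv_slope: float = 0.02             # mm^2 per mm^3
    noise_sd: float = 4000.0
    # vertex-wise surface measures
    mesh_subdivisions: int = 3          # 642 vertices per hemisphere
    effect_patch: str = "precentral"
    patch_amplitude: float = 0.25
    peak_age_vertex: float = 10.0
    vertex_noise_sd: float = 0.08
    # genotypes
    n_snps: int = 500
    causal_snp_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_sites <= 0 or self.n_snps < 0:
            raise ValueError("sizes must be positive")
        if len(self.ancestry_slopes) != self.k_ancestry:
            raise ValueError("ancestry_slopes length must equal k_ancestry")


@dataclasses.dataclass
class CohortFixture:
    """Paths of one generated fixture directory plus the truth sidecar."""

    out_dir: Path
    imaging_csv: Path
    super_csv: Path
    dictionary_csv: Path
    patterns_json: Path
    mesh_ply: dict[str, Path]
    vertex_csv: dict[str, Path]
    plink_prefix: Path
    genes_csv: Path
    truth_json: Path
    truth: dict


def age_curve(age: np.ndarray | float, peak: float, shape: float = 4.0) -> np.ndarray:
    """Smooth unimodal growth curve, value 1.0 exactly at ``peak``.

    Gamma-density shaped: rises from 0, peaks, then declines slowly —
    the qualitative trajectory of total cortical area over development.
    """
    a = np.asarray(age, float)
    r = np.clip(a / peak, 1e-9, None)
    return (r * np.exp(1.0 - r)) ** shape


def generate_genotypes(
    n_subjects: int, n_snps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Hardy-Weinberg genotypes: returns (calls, minor-allele freqs)."""
    maf = rng.uniform(0.05, 0.5, size=n_snps)
    calls = rng.binomial(2, maf[None, :], size=(n_subjects, n_snps)).astype(np.int8)
    return calls, maf


def generate_null_pvalue_sets(
    m: int, replicates: int, seed: int
) -> np.ndarray:
    """Uniform(0, 1] p-value vectors (replicates x m), seeded."""
    if m <= 0 or replicates <= 0:
        raise ValueError("m and replicates must be positive")
    rng = np.random.default_rng(seed)
    return 1.0 - rng.random((replicates, m))


def _octant_labels(local: np.ndarray) -> np.ndarray:
    idx = (
        (local[:, 0] > 0).astype(int) * 4
        + (local[:, 1] > 0).astype(int) * 2
        + (local[:, 2] > 0).astype(int)
    )
    return np.array([ROI_NAMES[i] for i in idx], dtype=object)


def _hemisphere_mesh(hemisphere: str, subdivisions: int) -> SurfaceMesh:
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=50.0)
    verts = np.asarray(ico.vertices, float)
    labels = _octant_labels(verts)
    shift = np.array([-60.0 if hemisphere == "lh" else 60.0, 0.0, 0.0])
    return SurfaceMesh(verts + shift, np.asarray(ico.faces, int), hemisphere, labels)


def _dictionary_rows(columns: list[str]) -> list[dict]:
    rows = []
    for name in columns:
        desc = f"Synthetic study measure {name}."
        links = ""
        if name.startswith("MRI_cort_area"):
            label = "Cortical area (mm2)"
            desc = "Cortical surface area derived from the structural scan (mm2)."
        elif name.startswith("MRI_cort_contrast"):
            label = "Cortical contrast"
            desc = "Gray/white intensity contrast at the cortical ribbon."
        elif name == "ICV":
            label = "Intracranial volume (mm3)"
        elif name == "Device_SerialNumber":
            label = "Scanner device"
            desc = "Serial number of the acquiring imaging device."
        elif name == "Age_At_IMGExam":
            label = "Age at imaging exam (years)"
        elif name == "Age_At_NPExam":
            label = "Age at neuropsych exam (years)"
        elif name == "Gender":
            label = "Gender"
        elif name == "Household_Income":
            label = "Household income (level)"
            desc = "Ordinal household income level (1=lowest)."
        elif name == "Parental_Education":
            label = "Parental education (level)"
            desc = "Ordinal highest parental education level (1=lowest)."
        elif name.startswith("GAF_"):
            label = f"Ancestry factor {name.split('_')[1]}"
            desc = "Genetic ancestry proportion; factors sum to 1 per subject."
        elif name.startswith("TBX_"):
            label = name.replace("TBX_", "Toolbox ").replace("_", " ")
            desc = "Cognitive toolbox score."
        elif name.startswith("PHX_"):
            label = name.replace("PHX_", "Self-report ").replace("_", " ")
            desc = "Self-report measure."
            links = "https://www.phenxtoolkit.org/"
        else:
            label = name
        rows.append(
            {"name": name, "axis_label": label, "description": desc, "links": links}
        )
    return rows


_PATTERNS = [
    {"label": "Imaging",
     "pattern": "(H_area|H_contrast|Acquisition)", "parent": None},
    {"label": "H_area", "pattern": "(^MRI_cort_area)", "parent": "Imaging"},
    {"label": "H_contrast", "pattern": "(^MRI_cort_contrast)", "parent": "Imaging"},
    {"label": "Acquisition",
     "pattern": "(^ICV$|^Device_|^Age_At_IMGExam$)", "parent": "Imaging"},
    {"label": "Demographics",
     "pattern": "(^Gender$|^Age_At_NPExam$)", "parent": None},
    {"label": "SES",
     "pattern": "(^Household_Income$|^Parental_Education$)", "parent": None},
    {"label": "Ancestry", "pattern": "(^GAF_)", "parent": None},
    {"label": "Cognition", "pattern": "(^TBX_)", "parent": None},
    {"label": "SelfReport", "pattern": "(^PHX_)", "parent": None},
]


def generate_cohort(params: SimulationParams, out_dir: str | Path) -> CohortFixture:
    """Write the full fixture directory; deterministic given the seed."""
    p = params
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(p.seed)
    n = p.n_subjects

    subj = np.array([f"S{i:04d}" for i in range(1, n + 1)])
    visit = np.array(["V1"] * n)
    age = rng.uniform(p.age_range[0], p.age_range[1], size=n).round(2)
    male = rng.random(n) < p.gender_balance
    gender = np.where(male, "M", "F")
    site = rng.integers(0, p.n_sites, size=n)
    device = np.array([f"SN_{s:02d}" for s in site])
    device_offsets = rng.normal(0.0, p.device_offset_sd, size=p.n_sites)
    income = rng.integers(1, p.ses_levels + 1, size=n).astype(float)
    education = rng.integers(1, p.ses_levels + 1, size=n).astype(float)
    gaf = rng.dirichlet(np.full(p.k_ancestry, p.dirichlet_alpha), size=n)
    icv = rng.normal(p.icv_mean, p.icv_sd, size=n).round(1)

    peak = np.where(male, p.peak_age_male, p.peak_age_female)
    r = age / peak
    curve = p.area_amplitude * (r * np.exp(1.0 - r)) ** p.curve_shape
    slopes = np.asarray(p.ancestry_slopes)
    area = (
        p.area_baseline
        + curve
        + p.gender_beta * male
        + device_offsets[site]
        + p.income_slope * income
        + p.education_slope * education
        + gaf @ slopes
        + p.icv_slope * (icv - p.icv_mean)
        + rng.normal(0.0, p.noise_sd, size=n)
    )

    # region-of-interest and contrast columns (small, partly age-driven)
    roi_cols = {}
    for roi in ROI_NAMES[:4]:
        roi_cols[f"MRI_cort_area.ctx.{roi}"] = (
            8000.0
            + 500.0 * age_curve(age, p.peak_age_vertex, p.curve_shape)
            + rng.normal(0.0, 300.0, size=n)
        ).round(2)
    for roi in ROI_NAMES[:2]:
        roi_cols[f"MRI_cort_contrast.ctx.{roi}"] = rng.normal(
            0.2, 0.02, size=n
        ).round(5)

    imaging = pd.DataFrame(
        {
            "SubjID": subj,
            "Visit": visit,
            "Age_At_IMGExam": age,
            "Device_SerialNumber": device,
            "ICV": icv,
            "MRI_cort_area.ctx.total": area.round(2),
            **roi_cols,
        }
    )

    tbx1 = (40.0 + 2.0 * age + rng.normal(0.0, 8.0, size=n)).round(2)
    tbx2 = (30.0 + 1.5 * age + rng.normal(0.0, 10.0, size=n)).round(2)
    phx = rng.normal(10.0, 3.0, size=n).round(2)
    income_col = income.copy()
    education_col = education.copy()
    income_col[rng.random(n) < p.ses_missing_rate] = np.nan
    education_col[rng.random(n) < p.ses_missing_rate] = np.nan
    super_df = pd.DataFrame(
        {
            "SubjID": subj,
            "Visit": visit,
            "Gender": gender,
            "Age_At_NPExam": (age + rng.uniform(0.0, 0.3, size=n)).round(2),
            "Household_Income": income_col,
            "Parental_Education": education_col,
            **{f"GAF_{k + 1}": gaf[:, k].round(6) for k in range(p.k_ancestry)},
            "TBX_picvocab_score": tbx1,
            "TBX_flanker_score": tbx2,
            "PHX_anxiety_score": phx,
        }
    )

    imaging_csv = out / "imaging.csv"
    super_csv = out / "super.csv"
    imaging.to_csv(imaging_csv, index=False)
    super_df.to_csv(super_csv, index=False)

    # dictionary over every measure column of both spreadsheets
    measure_cols = [c for c in imaging.columns if c not in ("SubjID", "Visit")]
    measure_cols += [c for c in super_df.columns if c not in ("SubjID", "Visit")]
    dictionary_csv = out / "dictionary.csv"
    pd.DataFrame(_dictionary_rows(measure_cols)).to_csv(dictionary_csv, index=False)
    patterns_json = out / "patterns.json"
    patterns_json.write_text(json.dumps(_PATTERNS, indent=1))

    # hemisphere meshes and vertex-wise area-expansion matrices
    mesh_ply: dict[str, Path] = {}
    vertex_csv: dict[str, Path] = {}
    vertex_effect = p.patch_amplitude * age_curve(
        age, p.peak_age_vertex, p.curve_shape
    )
    patch_sizes = {}
    for hemi in ("lh", "rh"):
        mesh = _hemisphere_mesh(hemi, p.mesh_subdivisions)
        mesh_ply[hemi] = out / f"{hemi}.ply"
        write_ply(mesh, mesh_ply[hemi])
        in_patch = (mesh.roi_labels == p.effect_patch).astype(float)
        patch_sizes[hemi] = int(in_patch.sum())
        values = (
            1.0
            + np.outer(vertex_effect, in_patch)
            + rng.normal(0.0, p.vertex_noise_sd, size=(n, mesh.n_vertices))
        )
        vdf = pd.DataFrame(
            values.round(6),
            columns=[f"v{j}" for j in range(mesh.n_vertices)],
            index=pd.MultiIndex.from_arrays([subj, visit], names=["SubjID", "Visit"]),
        )
        vertex_csv[hemi] = out / f"{hemi}_area_expansion.csv"
        VertexMeasureMatrix(vdf).to_csv(vertex_csv[hemi])

    # genotypes: scattered SNPs plus fixed clusters inside SHH and STON2
    calls, maf = generate_genotypes(n, p.n_snps, rng)
    snps: list[SNPRecord] = []
    shh = GENE_TABLE[0]
    ston2 = GENE_TABLE[1]
    special = [
        ("rs_shh_1", shh[1], shh[2] + 1_000),
        ("rs_shh_2", shh[1], shh[2] + 4_500),
        ("rs_shh_3", shh[1], shh[3] - 800),
        ("rs_ston2_1", ston2[1], ston2[2] + 5_000),
        ("rs_ston2_2", ston2[1], ston2[2] + 21_000),
        ("rs_ston2_3", ston2[1], ston2[3] - 2_000),
    ]
    bases = np.array(list("ACGT"))
    for j in range(p.n_snps):
        if j < len(special):
            name, chrom, bp = special[j]
        else:
            name = f"rs{100000 + j}"
            chrom = str(rng.integers(1, 23))
            bp = int(rng.integers(1_000_000, 200_000_000))
        a1, a2 = rng.choice(4, size=2, replace=False)
        snps.append(SNPRecord(name, chrom, bp, str(bases[a1]), str(bases[a2])))
    matrix = GenotypeMatrix(list(subj), snps, calls)
    plink_prefix = out / "cohort"
    write_plink(matrix, plink_prefix)
    genes_csv = out / "genes.csv"
    pd.DataFrame(
        GENE_TABLE, columns=["name", "chromosome", "start_bp", "end_bp"]
    ).to_csv(genes_csv, index=False)

    # realized recovery targets
    f_m = age_curve(age[male], p.peak_age_male, p.curve_shape)
    f_f = age_curve(age[male], p.peak_age_female, p.curve_shape)
    gender_target = p.gender_beta + p.area_amplitude * float(np.mean(f_m - f_f))
    truth = {
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(p).items()
        },
        "device_offsets": device_offsets.round(6).tolist(),
        "gender_coefficient_target": round(gender_target, 6),
        "income_slope": p.income_slope,
        "education_slope": p.education_slope,
        "icv_slope": p.icv_slope,
        "peak_age_male": p.peak_age_male,
        "peak_age_female": p.peak_age_female,
        "peak_age_vertex": p.peak_age_vertex,
        "effect_patch": p.effect_patch,
        "patch_vertex_counts": patch_sizes,
        "real_effect_blocks": ["device", "ses", "ancestry", "gender_icv"],
        "snp_maf_first6": maf[:6].round(6).tolist(),
        "causal_snp_effect": p.causal_snp_effect,
    }
    truth_json = out / "truth.json"
    truth_json.write_text(json.dumps(truth, indent=1, sort_keys=True))

    return CohortFixture(
        out_dir=out,
        imaging_csv=imaging_csv,
        super_csv=super_csv,
        dictionary_csv=dictionary_csv,
        patterns_json=patterns_json,
        mesh_ply=mesh_ply,
        vertex_csv=vertex_csv,
        plink_prefix=plink_prefix,
        genes_csv=genes_csv,
        truth_json=truth_json,
        truth=truth,
    )
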