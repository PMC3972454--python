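"""Vertex-wise cortical surface statistics.

The same additive model used for region-of-interest analysis is run
independently at every vertex of a labeled hemisphere mesh, with the
per-vertex measure (thickness, area-expansion or volume-expansion
factor) as the dependent variable.  The result is a set of statistical
surface maps — p-values for the independent variable, the interaction
main effect and the interaction itself, plus predicted-value frames
over the independent-variable range — which are thresholded by
Benjamini-Hochberg FDR, colormapped with step-wise linear transfer
functions (sub-threshold vertices in neutral gray), differentiated into
instantaneous rate-of-change maps, or turned into deformed geometry.

Because only the response changes from vertex to vertex, the design
matrix and its per-penalty factorizations are computed once and reused,
which keeps mass-univariate fitting fast.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .cohort import CohortTable, complete_cases
from .gam import DEFAULT_LAM_GRID, FitInternals, block_pvalue, build_design
from .models import ModelTerms, _reference_row
from . import render

__all__ = [
    "SurfaceMesh",
    "VertexMeasureMatrix",
    "VertexMapSet",
    "ColormapSpec",
    "read_ply",
    "write_ply",
    "fit_per_vertex",
    "fdr_threshold",
    "neglog10_map",
    "apply_colormap",
    "rate_of_change",
    "closest_region",
    "deform_geometry",
    "vertex_normals",
    "export_map_image",
    "FIGURE_COLLAGE_VIEWS",
]


class SurfaceError(ValueError):
    pass


#: publication collage view sequence: superior, right lateral x2, right
#: medial x2, left medial x2, left lateral x2, inferior
FIGURE_COLLAGE_VIEWS: tuple[tuple[str, str], ...] = (
    ("superior", "both"),
    ("lateral", "rh"),
    ("lateral", "rh"),
    ("medial", "rh"),
    ("medial", "rh"),
    ("medial", "lh"),
    ("medial", "lh"),
    ("lateral", "lh"),
    ("lateral", "lh"),
    ("inferior", "both"),
)


@dataclasses.dataclass
class SurfaceMesh:
    """Triangular hemisphere mesh with per-vertex region labels."""

    vertices: np.ndarray          # (N, 3) mm
    faces: np.ndarray             # (M, 3) vertex indices
    hemisphere: str = "lh"        # "lh" | "rh"
    roi_labels: np.ndarray | None = None  # (N,) region names; "unknown" allowed

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        self.faces = np.asarray(self.faces, int)
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise SurfaceError("face indices out of vertex range")
        if self.hemisphere not in ("lh", "rh"):
            raise SurfaceError(f"hemisphere must be 'lh' or 'rh', got {self.hemisphere!r}")
        if self.roi_labels is None:
            self.roi_labels = np.full(n, "unknown", dtype=object)
        else:
            self.roi_labels = np.asarray(self.roi_labels, dtype=object)
            if len(self.roi_labels) != n:
                raise SurfaceError("roi_labels length must equal vertex count")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


# ---------------------------------------------------------------------------
# ascii-PLY I/O with per-vertex integer region labels and float scalars
# ---------------------------------------------------------------------------

def write_ply(
    mesh: SurfaceMesh, path: str | Path, scalars: dict[str, np.ndarray] | None = None
) -> None:
    scalars = scalars or {}
    labels = list(dict.fromkeys(mesh.roi_labels))
    label_id = {name: i for i, name in enumerate(labels)}
    lines = [
        "ply",
        "format ascii 1.0",
        f"comment hemisphere {mesh.hemisphere}",
    ]
    lines += [f"comment region {i} {name}" for name, i in label_id.items()]
    lines += [
        f"element vertex {mesh.n_vertices}",
        "property float x",
        "property float y",
        "property float z",
        "property int region",
    ]
    lines += [f"property float {name}" for name in scalars]
    lines += [
        f"element face {len(mesh.faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    cols = [mesh.vertices[:, 0], mesh.vertices[:, 1], mesh.vertices[:, 2]]
    region = np.array([label_id[l] for l in mesh.roi_labels])
    for i in range(mesh.n_vertices):
        row = f"{cols[0][i]:.6f} {cols[1][i]:.6f} {cols[2][i]:.6f} {region[i]}"
        for name in scalars:
            row += f" {float(scalars[name][i]):.8g}"
        lines.append(row)
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ply(path: str | Path) -> tuple[SurfaceMesh, dict[str, np.ndarray]]:
    text = Path(path).read_text().splitlines()
    if not text or text[0].strip() != "ply":
        raise SurfaceError(f"{path}: not a PLY file")
    hemisphere = "lh"
    label_names: dict[int, str] = {}
    n_vert = n_face = 0
    vertex_props: list[str] = []
    i = 1
    in_vertex = False
    while i < len(text):
        line = text[i].strip()
        i += 1
        if line == "end_header":
            break
        parts = line.split()
        if parts[0] == "comment":
            if parts[1] == "hemisphere":
                hemisphere = parts[2]
            elif parts[1] == "region":
                label_names[int(parts[2])] = " ".join(parts[3:])
        elif parts[0] == "element":
            if parts[1] == "vertex":
                n_vert = int(parts[2])
                in_vertex = True
            else:
                n_face = int(parts[2])
                in_vertex = False
        elif parts[0] == "property" and in_vertex and parts[1] != "list":
            vertex_props.append(parts[2])
    data = np.array(
        [[float(v) for v in text[j].split()] for j in range(i, i + n_vert)]
    )
    verts = data[:, :3]
    cols = {name: data[:, k] for k, name in enumerate(vertex_props)}
    region = cols.get("region")
    labels = None
    if region is not None:
        labels = np.array([label_names.get(int(r), "unknown") for r in region],
                          dtype=object)
    scalars = {
        name: cols[name]
        for name in vertex_props
        if name not in ("x", "y", "z", "region")
    }
    faces = np.array(
        [[int(v) for v in text[j].split()[1:4]] for j in range(i + n_vert, i + n_vert + n_face)]
    ) if n_face else np.zeros((0, 3), int)
    return SurfaceMesh(verts, faces, hemisphere, labels), scalars


@dataclasses.dataclass
class VertexMeasureMatrix:
    """Sessions x vertices measure matrix (columns v0..v{N-1})."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not all(c.startswith("v") for c in self.data.columns):
            raise SurfaceError("vertex columns must be named v0..v{N-1}")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)

    def to_csv(self, path: str | Path) -> None:
        self.data.reset_index().to_csv(path, index=False, float_format="%.8g")

    @classmethod
    def from_csv(cls, path: str | Path,
                 key_columns: Sequence[str] = ("SubjID", "Visit")) -> "VertexMeasureMatrix":
        df = pd.read_csv(path).set_index(list(key_columns))
        return cls(df)


@dataclasses.dataclass
class VertexMapSet:
    """Per-vertex statistical maps from a mass-univariate model run."""

    p_independent: np.ndarray
    effect: np.ndarray
    predicted_frames: np.ndarray        # (F, N)
    grid: np.ndarray                    # (F,) independent values
    p_interaction_main: np.ndarray | None = None
    p_interaction: np.ndarray | None = None
    n_sessions: int = 0

    @property
    def n_vertices(self) -> int:
        return len(self.p_independent)


def fit_per_vertex(
    view: CohortTable | pd.DataFrame,
    model_terms: ModelTerms,
    vmm: VertexMeasureMatrix,
    n_frames: int = 17,
    lam_grid: np.ndarray | None = None,
) -> VertexMapSet:
    """Run the model at every vertex of the measure matrix.

    The dependent variable of ``model_terms`` is replaced by each vertex
    column in turn.  Sessions are the intersection of the view's
    complete-case rows (over the predictors) and the matrix rows.
    Vertices with a constant measure are degenerate: they get p = 1 and
    zero effect.  The design factorizations are shared across vertices;
    only the smoothing weight is chosen per vertex (by GCV).
    """
    from .gam import term_variables

    predictors = term_variables(model_terms.terms)
    df = view.data if isinstance(view, CohortTable) else view
    missing = [v for v in predictors if v not in df.columns]
    if missing:
        raise SurfaceError(f"view lacks predictor column(s): {', '.join(missing)}")
    df = df.dropna(subset=predictors)
    common = df.index.intersection(vmm.data.index)
    if len(common) == 0:
        raise SurfaceError("no overlapping sessions between view and vertex matrix")
    df = df.loc[common]
    Y = vmm.data.loc[common].to_numpy(float)
    n, n_vertices = Y.shape

    design = build_design(df, model_terms.terms)
    X, S = design.X, design.S
    p = X.shape[1]
    if n <= p:
        raise SurfaceError(f"need more sessions ({n}) than coefficients ({p})")
    xtx = X.T @ X
    XtY = X.T @ Y                                   # (p, N)
    yty = np.einsum("ij,ij->j", Y, Y)               # (N,)
    grid_lams = (
        np.asarray(lam_grid if lam_grid is not None else DEFAULT_LAM_GRID, float)
        if design.has_smooth
        else np.array([0.0])
    )
    # shared per-lambda factorizations
    pre = []
    for lam in grid_lams:
        a = xtx + lam * S
        try:
            cf = sla.cho_factor(a)
        except sla.LinAlgError:
            continue
        ainv = sla.cho_solve(cf, np.eye(p))
        ainv_xtx = ainv @ xtx
        pre.append(
            {
                "lam": lam,
                "ainv": ainv,
                "ainv_xtx": ainv_xtx,
                "edf": float(np.trace(ainv_xtx)),
                "edf_diag": np.diag(ainv_xtx).copy(),
                "cov0": ainv @ xtx @ ainv,  # multiply by sigma2 per vertex
            }
        )
    if not pre:
        raise SurfaceError("design is numerically singular")

    # betas for all lambdas at once: (L, p, N)
    betas = np.stack([pr["ainv"] @ XtY for pr in pre])
    # rss per lambda per vertex
    rss = np.empty((len(pre), n_vertices))
    for li in range(len(pre)):
        b = betas[li]
        rss[li] = yty - 2 * np.einsum("pn,pn->n", b, XtY) + np.einsum(
            "pn,pq,qn->n", b, xtx, b
        )
    rss = np.maximum(rss, 0.0)
    edfs = np.array([pr["edf"] for pr in pre])
    gcv = n * rss / np.maximum(n - edfs, 1e-10)[:, None] ** 2
    best = np.argmin(gcv, axis=0)

    roles = {t["role"] for t in
             ({"role": getattr(b.term, "role", None)} for b in design.blocks)}
    want_main = "interaction_main" in roles
    want_inter = "interaction" in roles

    p_indep = np.ones(n_vertices)
    p_main = np.ones(n_vertices) if want_main else None
    p_inter = np.ones(n_vertices) if want_inter else None
    effect = np.zeros(n_vertices)

    # prediction grid at covariate reference values
    indep = model_terms.terms[0].name
    x = np.asarray(df[indep], float)
    grid = np.linspace(x.min(), x.max(), n_frames)
    ref = _reference_row(df, skip=[indep])
    frame_df = pd.DataFrame({indep: grid, **{c: np.repeat(v, n_frames)
                                             for c, v in ref.items()}})
    Xg = design.transform(frame_df)                 # (F, p)
    frames = np.empty((n_frames, n_vertices))

    degenerate = np.ptp(Y, axis=0) <= 1e-12
    gvar = float(np.var(grid))

    for v in range(n_vertices):
        if degenerate[v]:
            frames[:, v] = Y[:, v].mean()
            continue
        pr = pre[best[v]]
        beta = betas[best[v], :, v]
        sigma2 = rss[best[v], v] / max(n - pr["edf"], 1e-10)
        internals = FitInternals(
            beta=beta,
            lam=pr["lam"],
            edf=pr["edf"],
            rss=rss[best[v], v],
            gcv=gcv[best[v], v],
            sigma2=sigma2,
            cov=sigma2 * pr["cov0"],
            edf_per_coef=pr["edf_diag"],
            fitted=np.empty(0),
        )
        for b in design.blocks:
            role = getattr(b.term, "role", None)
            if role == "independent":
                p_indep[v] = block_pvalue(internals, b.sl, b.penalized, n)[0]
            elif role == "interaction_main" and want_main:
                p_main[v] = block_pvalue(internals, b.sl, b.penalized, n)[0]
            elif role == "interaction" and want_inter:
                p_inter[v] = block_pvalue(internals, b.sl, b.penalized, n)[0]
        fv = Xg @ beta
        frames[:, v] = fv
        effect[v] = float(np.cov(grid, fv, bias=True)[0, 1] / gvar)

    clamp = np.finfo(float).tiny
    p_indep = np.clip(p_indep, clamp, 1.0)
    if p_main is not None:
        p_main = np.clip(p_main, clamp, 1.0)
    if p_inter is not None:
        p_inter = np.clip(p_inter, clamp, 1.0)
    return VertexMapSet(
        p_independent=p_indep,
        effect=effect,
        predicted_frames=frames,
        grid=grid,
        p_interaction_main=p_main,
        p_interaction=p_inter,
        n_sessions=n,
    )


# ---------------------------------------------------------------------------
# FDR and maps
# ---------------------------------------------------------------------------

def fdr_threshold(pvals: np.ndarray, q: float = 0.05) -> float:
    """Benjamini-Hochberg p-value threshold.

    Largest p(i) with p(i) <= (i/m) q over the sorted p-values; returns
    0.0 when nothing passes (the no-rejection sentinel).
    """
    if not 0 < q < 1:
        raise SurfaceError(f"q must be in (0,1), got {q}")
    p = np.asarray(pvals, float).ravel()
    if p.size == 0:
        raise SurfaceError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise SurfaceError("p-values must lie in (0, 1]")
    ps = np.sort(p)
    m = ps.size
    crit = q * np.arange(1, m + 1) / m
    passing = np.nonzero(ps <= crit)[0]
    if passing.size == 0:
        return 0.0
    return float(ps[passing[-1]])


def neglog10_map(pvals: np.ndarray | float) -> np.ndarray | float:
    """Elementwise -log10(p); p = 1 maps to 0.  p <= 0 is an error."""
    p = np.asarray(pvals, float)
    if (p <= 0).any() or (p > 1).any():
        raise SurfaceError("p-values must lie in (0, 1]")
    out = -np.log10(p)
    return float(out) if np.isscalar(pvals) or out.ndim == 0 else out


@dataclasses.dataclass
class ColormapSpec:
    """Step-wise linear transfer function with a sub-threshold gray."""

    stops: list[tuple[float, tuple[int, int, int]]]
    sub_threshold_color: tuple[int, int, int] = (128, 128, 128)
    threshold: float = 1.3010299956639813  # -log10(0.05)

    def __post_init__(self) -> None:
        if len(self.stops) < 2:
            raise SurfaceError("a colormap needs at least 2 stops")
        vals = [v for v, _ in self.stops]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise SurfaceError("colormap stop values must be strictly increasing")


def apply_colormap(
    values: np.ndarray,
    cmap: ColormapSpec,
    significant_mask: np.ndarray,
) -> np.ndarray:
    """Map values to N x 4 RGBA; non-significant vertices get neutral gray."""
    values = np.asarray(values, float)
    mask = np.asarray(significant_mask, bool)
    if values.shape != mask.shape:
        raise SurfaceError("values and mask must have the same length")
    xs = np.array([v for v, _ in cmap.stops], float)
    colors = np.array([c for _, c in cmap.stops], float)
    out = np.empty((values.size, 4), dtype=np.uint8)
    out[:, 3] = 255
    for ch in range(3):
        out[:, ch] = np.clip(
            np.interp(values, xs, colors[:, ch]), 0, 255
        ).astype(np.uint8)
    out[~mask, :3] = np.array(cmap.sub_threshold_color, dtype=np.uint8)
    return out


def rate_of_change(predicted_frames: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Instantaneous rate of change of the prediction w.r.t. the predictor.

    Central finite differences (one-sided at the ends), per vertex.
    Exact for frames linear in the grid.
    """
    frames = np.asarray(predicted_frames, float)
    grid = np.asarray(grid, float)
    if frames.shape[0] < 3:
        raise SurfaceError("need at least 3 frames to differentiate")
    if (np.diff(grid) <= 0).any():
        raise SurfaceError("grid must be strictly increasing")
    return np.gradient(frames, grid, axis=0)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _edges_by_vertex(mesh: SurfaceMesh) -> list[set[int]]:
    neigh: list[set[int]] = [set() for _ in range(mesh.n_vertices)]
    for a, b, c in mesh.faces:
        neigh[a].update((b, c))
        neigh[b].update((a, c))
        neigh[c].update((a, b))
    return neigh


def closest_region(mesh: SurfaceMesh, vertex_index: int) -> tuple[str, np.ndarray]:
    """Region name at (or nearest to) a vertex, plus the region's outline.

    Unlabeled ("unknown") vertices take the label of the nearest labeled
    vertex by Euclidean distance.  The boundary set contains the region's
    vertices that have at least one differently-labeled neighbor.
    """
    n = mesh.n_vertices
    if not 0 <= vertex_index < n:
        raise SurfaceError(f"vertex index {vertex_index} out of range [0, {n})")
    labels = mesh.roi_labels
    label = labels[vertex_index]
    if label == "unknown":
        labeled = np.nonzero(labels != "unknown")[0]
        if labeled.size == 0:
            return "unknown", np.array([], int)
        d = np.linalg.norm(
            mesh.vertices[labeled] - mesh.vertices[vertex_index], axis=1
        )
        label = labels[labeled[np.argmin(d)]]
    neigh = _edges_by_vertex(mesh)
    boundary = np.array(
        [
            v
            for v in range(n)
            if labels[v] == label and any(labels[u] != label for u in neigh[v])
        ],
        int,
    )
    return str(label), boundary


def vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Area-weighted average of incident face normals, unit length."""
    v = mesh.vertices
    f = mesh.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    out = np.zeros_like(v)
    for k in range(3):
        np.add.at(out, f[:, k], fn)
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return out / norms


def deform_geometry(
    mesh: SurfaceMesh, predicted_map: np.ndarray, scale: float
) -> SurfaceMesh:
    """Displace vertices along their normals by the mean-centred map.

    Shows "geometry as a predicted variable": regions above the map mean
    bulge outward, regions below sink inward.  Pure function; the input
    mesh is untouched.
    """
    pm = np.asarray(predicted_map, float)
    if pm.shape != (mesh.n_vertices,):
        raise SurfaceError("predicted map length must equal vertex count")
    if scale <= 0:
        raise SurfaceError("scale must be positive")
    disp = scale * (pm - pm.mean())
    new_vertices = mesh.vertices + disp[:, None] * vertex_normals(mesh)
    return SurfaceMesh(
        new_vertices, mesh.faces.copy(), mesh.hemisphere, mesh.roi_labels.copy()
    )


def export_map_image(
    mesh: SurfaceMesh,
    rgba: np.ndarray,
    view: str,
    out_path: str | Path,
    size: int = 400,
) -> Path:
    """Render one view to a PNG with alpha-0 background; deterministic."""
    from PIL import Image

    rgba = np.asarray(rgba)
    if rgba.shape != (mesh.n_vertices, 4):
        raise SurfaceError("rgba must be (n_vertices, 4)")
    rot = render.view_rotation(view, mesh.hemisphere)
    img = render.rasterize(mesh.vertices, mesh.faces, rgba, rot, size=size)
    out_path = Path(out_path)
    try:
        Image.fromarray(img, "RGBA").save(out_path, format="PNG")
    except OSError as exc:
        raise SurfaceError(f"cannot write image to {out_path}: {exc}") from exc
    return out_path
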