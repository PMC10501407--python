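"""CoMSIA-style 3D-QSAR: alignment, Gaussian similarity fields, PLS.

Aligned molecules are sampled on a regular cubic grid (default pitch 2 Å,
box extended 4 Å beyond the molecules in every direction).  At each grid
point q and for each of five property fields — steric (S), electrostatic
(E), hydrophobic (H), H-bond donor (D), H-bond acceptor (A) — a similarity
index is computed against a probe atom:

    A_F(q) = - sum_atoms  w_probe * w_atom * exp(-alpha * r(atom, q)^2)

with attenuation alpha = 0.3 1/Å² and no distance cutoff (the Gaussian
decays smoothly, which is what makes the index insensitive to small
alignment errors).  The stacked per-compound field rows form a wide,
heavily collinear matrix that is regressed on activity by partial least
squares; model quality is judged by leave-one-out Q², the optimal number of
components (ONC), non-cross-validated R², SEE and F, and the per-field
contribution fractions.  Contour maps mark grid points whose
coefficient·stdev product falls in the favored/disfavored percentile tails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cross_decomposition import PLSRegression

FIELD_LABELS = ("S", "E", "H", "D", "A")

DEFAULT_ALPHA = 0.3  # attenuation, 1/Å^2
DEFAULT_SPACING = 2.0  # grid pitch, Å
DEFAULT_MARGIN = 4.0  # box extension, Å
DEFAULT_MIN_SIGMA = 0.05  # column stdev floor, similarity units

#: probe atom weights per field (radius 1 Å -> steric weight 1, charge +1,
#: hydrophobicity +1, donor/acceptor +1)
PROBE_WEIGHTS = {"S": 1.0, "E": 1.0, "H": 1.0, "D": 1.0, "A": 1.0}

#: Bondi van der Waals radii (Å)
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}

#: simple atom-typed hydrophobicity parameters (dimensionless; carbons and
#: halogens hydrophobic, heteroatoms hydrophilic)
HYDROPHOBICITY = {
    "C": 0.5, "H": 0.0, "F": 0.3, "Cl": 0.4, "Br": 0.4, "I": 0.4,
    "N": -0.5, "O": -0.6, "S": 0.1, "P": 0.0,
}


@dataclass
class AlignedMolecule:
    """A molecule in the common reference frame with per-atom field
    properties."""

    id: str
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3), Å
    charges: np.ndarray  # partial charges, e
    radii: np.ndarray  # vdW radii, Å
    hydrophobicity: np.ndarray
    donor: np.ndarray  # bool
    acceptor: np.ndarray  # bool
    scaffold_map: list[int] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.elements)
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError(f"molecule {self.id}: non-finite coordinates")
        for nm in ("charges", "radii", "hydrophobicity"):
            arr = np.asarray(getattr(self, nm), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"molecule {self.id}: {nm} length != n_atoms")
            setattr(self, nm, arr)
        if (self.radii <= 0).any():
            raise ValueError(f"molecule {self.id}: vdW radii must be > 0")
        self.donor = np.asarray(self.donor, dtype=bool)
        self.acceptor = np.asarray(self.acceptor, dtype=bool)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def atom_weights(self, field: str) -> np.ndarray:
        if field == "S":
            return self.radii**3
        if field == "E":
            return self.charges
        if field == "H":
            return self.hydrophobicity
        if field == "D":
            return self.donor.astype(float)
        if field == "A":
            return self.acceptor.astype(float)
        raise KeyError(f"unknown field {field!r} (expected one of {FIELD_LABELS})")

    def translated(self, shift: np.ndarray) -> "AlignedMolecule":
        return AlignedMolecule(
            id=self.id,
            elements=list(self.elements),
            coords=self.coords + np.asarray(shift, dtype=float),
            charges=self.charges.copy(),
            radii=self.radii.copy(),
            hydrophobicity=self.hydrophobicity.copy(),
            donor=self.donor.copy(),
            acceptor=self.acceptor.copy(),
            scaffold_map=list(self.scaffold_map) if self.scaffold_map else None,
        )


def default_properties(elements: Sequence[str]) -> dict[str, np.ndarray]:
    """Rule-table properties for atoms without an explicit property table:
    Bondi radii, zero charge, element-typed hydrophobicity, N/O acceptors."""
    radii = np.array([BONDI_RADII.get(e, 1.7) for e in elements])
    hydro = np.array([HYDROPHOBICITY.get(e, 0.0) for e in elements])
    acceptor = np.array([e in ("N", "O") for e in elements])
    return {
        "charges": np.zeros(len(elements)),
        "radii": radii,
        "hydrophobicity": hydro,
        "donor": np.zeros(len(elements), dtype=bool),
        "acceptor": acceptor,
    }


# ---------------------------------------------------------------------------
# Rigid alignment (Kabsch)


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation mapping centered P onto centered Q (SVD with
    determinant correction)."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def align_to_template(
    mol: AlignedMolecule,
    template: AlignedMolecule,
    atom_map: Sequence[tuple[int, int]],
) -> tuple[AlignedMolecule, float]:
    """Rigid-body least-squares superposition of ``mol`` onto ``template``
    over the mapped atom pairs; returns the aligned copy and scaffold RMSD.

    ``atom_map`` pairs are (mol_atom_index, template_atom_index); at least 3
    non-collinear pairs are required to fix the rotation.
    """
    if len(atom_map) < 3:
        raise ValueError("atom_map needs at least 3 pairs")
    mi = [i for i, _ in atom_map]
    ti = [j for _, j in atom_map]
    P = mol.coords[mi]
    Q = template.coords[ti]
    Pc = P - P.mean(axis=0)
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2:
        raise ValueError("mapped atoms are collinear; rotation is degenerate")
    Qc = Q - Q.mean(axis=0)
    R = kabsch_rotation(Pc, Qc)
    new_coords = (mol.coords - P.mean(axis=0)) @ R.T + Q.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((new_coords[mi] - Q) ** 2, axis=1))))
    out = AlignedMolecule(
        id=mol.id,
        elements=list(mol.elements),
        coords=new_coords,
        charges=mol.charges.copy(),
        radii=mol.radii.copy(),
        hydrophobicity=mol.hydrophobicity.copy(),
        donor=mol.donor.copy(),
        acceptor=mol.acceptor.copy(),
        scaffold_map=mi,
    )
    return out, rmsd


# ---------------------------------------------------------------------------
# Grid and fields


@dataclass(frozen=True)
class FieldGrid:
    """Regular cubic grid: origin, pitch, and per-axis point counts."""

    origin: tuple[float, float, float]
    spacing: float
    counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.counts
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All grid points, z varying fastest (OpenDX ordering)."""
        nx, ny, nz = self.counts
        o = np.asarray(self.origin)
        ax = [o[d] + self.spacing * np.arange(self.counts[d]) for d in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


def build_grid(
    molecules: Sequence[AlignedMolecule],
    spacing: float = DEFAULT_SPACING,
    margin: float = DEFAULT_MARGIN,
) -> FieldGrid:
    """Axis-aligned box covering every molecule, extended by ``margin`` on
    all sides; per-axis count = floor(extent/spacing) + 1.  Invariant under
    molecule reordering."""
    if not molecules:
        raise ValueError("need at least one molecule")
    allc = np.vstack([m.coords for m in molecules])
    lo = allc.min(axis=0) - margin
    hi = allc.max(axis=0) + margin
    counts = tuple(int(np.floor((hi[d] - lo[d]) / spacing + 1e-9)) + 1 for d in range(3))
    return FieldGrid(origin=tuple(float(v) for v in lo), spacing=float(spacing),
                     counts=counts)


def compute_field(
    mol: AlignedMolecule,
    grid: FieldGrid,
    field: str,
    alpha: float = DEFAULT_ALPHA,
) -> np.ndarray:
    """Similarity indices of one molecule for one field over all grid
    points (CoMSIA sign convention: the probe/atom sum is negated)."""
    w_atom = mol.atom_weights(field)
    if not np.isfinite(w_atom).all():
        bad = int(np.where(~np.isfinite(w_atom))[0][0])
        raise ValueError(
            f"molecule {mol.id}: atom {bad} has no finite {field!r} property"
        )
    d2 = cdist(grid.points(), mol.coords, "sqeuclidean")
    return -PROBE_WEIGHTS[field] * (np.exp(-alpha * d2) @ w_atom)


@dataclass
class FieldMatrix:
    """Stacked field rows: one row per compound, one column per
    (field, grid point); ``active_mask`` drops near-constant columns."""

    compound_ids: list[str]
    grid: FieldGrid
    field_labels: tuple[str, ...]
    values: np.ndarray  # (n_compounds, n_fields * n_points)
    active_mask: np.ndarray  # bool over columns
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("field matrix contains non-finite values")
        npts = self.grid.n_points
        if self.values.shape != (len(self.compound_ids), len(self.field_labels) * npts):
            raise ValueError("field matrix shape inconsistent with grid/fields")

    @property
    def n_points(self) -> int:
        return self.grid.n_points

    def column_field(self, col: int) -> str:
        return self.field_labels[col // self.n_points]

    def column_point(self, col: int) -> int:
        return col % self.n_points

    def field_block(self, label: str) -> slice:
        i = self.field_labels.index(label)
        return slice(i * self.n_points, (i + 1) * self.n_points)

    @property
    def active_values(self) -> np.ndarray:
        return self.values[:, self.active_mask]


def molecule_field_row(
    mol: AlignedMolecule,
    grid: FieldGrid,
    field_labels: Sequence[str] = FIELD_LABELS,
    alpha: float = DEFAULT_ALPHA,
) -> np.ndarray:
    return np.concatenate([compute_field(mol, grid, f, alpha) for f in field_labels])


def assemble_field_matrix(
    molecules: Sequence[AlignedMolecule],
    grid: FieldGrid | None = None,
    alpha: float = DEFAULT_ALPHA,
    min_sigma: float = DEFAULT_MIN_SIGMA,
    field_labels: Sequence[str] = FIELD_LABELS,
) -> FieldMatrix:
    """Stack per-compound field rows and mask columns whose standard
    deviation falls below ``min_sigma`` (they carry no contrast)."""
    if grid is None:
        grid = build_grid(molecules)
    rows = np.vstack([molecule_field_row(m, grid, field_labels, alpha) for m in molecules])
    sd = rows.std(axis=0)
    mask = sd >= min_sigma
    return FieldMatrix(
        compound_ids=[m.id for m in molecules],
        grid=grid,
        field_labels=tuple(field_labels),
        values=rows,
        active_mask=mask,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# PLS


@dataclass
class PlsQsarModel:
    """PLS model over active field columns with LOO diagnostics.

    ``coefficients`` live on the active columns; prediction is
    ``(x_active - x_mean) @ coefficients + y_mean``.  ``fractions`` are the
    normalized per-field sums of |coefficient|·stdev and sum to 1.
    """

    n_components: int
    coefficients: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    column_sd: np.ndarray  # stdev of active columns
    q2: float
    q2_per_component: list[float]
    r2: float
    see: float
    f_value: float
    fractions: dict[str, float]
    active_mask: np.ndarray
    field_labels: tuple[str, ...]
    grid: FieldGrid
    alpha: float = DEFAULT_ALPHA
    stats_source: str = "fitted"

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("ONC must be >= 1")
        if self.q2 > 1 + 1e-9:
            raise ValueError("q2 cannot exceed 1")
        tot = sum(self.fractions.values())
        if self.fractions and abs(tot - 1.0) > 1e-9:
            raise ValueError(f"field fractions must sum to 1 (got {tot})")

    def predict_rows(self, active_rows: np.ndarray) -> np.ndarray:
        active_rows = np.atleast_2d(np.asarray(active_rows, dtype=float))
        return (active_rows - self.x_mean) @ self.coefficients + self.y_mean

    def predict_molecule(self, mol: AlignedMolecule) -> float:
        row = molecule_field_row(mol, self.grid, self.field_labels, self.alpha)
        return float(self.predict_rows(row[self.active_mask][None, :])[0])


def _pls_fit_predict(
    X: np.ndarray, y: np.ndarray, c: int, X_new: np.ndarray
) -> np.ndarray:
    m = PLSRegression(n_components=c, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m.fit(X, y)
    return m.predict(np.atleast_2d(X_new)).ravel()


def fit_pls(
    matrix: FieldMatrix,
    y: np.ndarray,
    max_components: int = 10,
) -> PlsQsarModel:
    """Scan component counts by LOO Q², pick the ONC (argmax, smallest on
    ties), and refit without cross-validation for R², SEE and F.

    SEE = sqrt(RSS/(n-c-1)) and F = (R²/c) / ((1-R²)/(n-c-1)) at c = ONC.
    """
    y = np.asarray(y, dtype=float)
    X = matrix.active_values
    n = len(y)
    if X.shape[1] == 0:
        raise ValueError("field matrix has no active columns")
    if n < 4:
        raise ValueError("need at least 4 compounds")
    if y.std() <= 0:
        raise ValueError("degenerate response: zero variance")
    if max_components >= n - 1:
        raise ValueError(f"max_components must be < n-1 (n={n})")
    c_max = min(max_components, n - 2, X.shape[1])
    tss = float(np.sum((y - y.mean()) ** 2))
    q2s: list[float] = []
    for c in range(1, c_max + 1):
        press = 0.0
        for i in range(n):
            keep = np.arange(n) != i
            pred = _pls_fit_predict(X[keep], y[keep], c, X[i])
            press += float((y[i] - pred[0]) ** 2)
        q2s.append(1.0 - press / tss)
    onc = int(np.argmax(q2s)) + 1  # smallest c on ties (argmax takes first)

    m = PLSRegression(n_components=onc, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m.fit(X, y)
    yhat = m.predict(X).ravel()
    rss = float(np.sum((y - yhat) ** 2))
    r2 = 1.0 - rss / tss
    dof = n - onc - 1
    see = float(np.sqrt(rss / dof)) if dof > 0 else float("nan")
    f_value = (r2 / onc) / ((1.0 - r2) / dof) if dof > 0 and r2 < 1 else float("inf")
    coef = np.asarray(m.coef_).reshape(-1)
    sd = X.std(axis=0)

    # per-field contribution: normalized sum of |coef| * column stdev
    contrib: dict[str, float] = {}
    active_cols = np.where(matrix.active_mask)[0]
    for label in matrix.field_labels:
        block = matrix.field_block(label)
        in_field = (active_cols >= block.start) & (active_cols < block.stop)
        contrib[label] = float(np.sum(np.abs(coef[in_field]) * sd[in_field]))
    total = sum(contrib.values())
    if total > 0:
        fractions = {k: v / total for k, v in contrib.items()}
        # exact renormalization against rounding drift
        s = sum(fractions.values())
        fractions = {k: v / s for k, v in fractions.items()}
    else:
        fractions = {k: 1.0 / len(contrib) for k in contrib}

    return PlsQsarModel(
        n_components=onc,
        coefficients=coef,
        x_mean=X.mean(axis=0),
        y_mean=float(y.mean()),
        column_sd=sd,
        q2=float(q2s[onc - 1]),
        q2_per_component=[float(v) for v in q2s],
        r2=float(r2),
        see=see,
        f_value=float(f_value),
        fractions=fractions,
        active_mask=matrix.active_mask.copy(),
        field_labels=matrix.field_labels,
        grid=matrix.grid,
        alpha=matrix.alpha,
    )


#: The published CoMSIA statistics for the dihydropteridone model, carried
#: as metadata (the commercial field/alignment pipeline behind them is not
#: reproducible).  The source reports Q² = 0.682 in its statistics table and
#: 0.628 in the running text; both readings are recorded.  The printed field
#: contributions sum to 1.215, not 1 — our fitted fractions are normalized
#: by contract.
PUBLISHED_COMSIA_STATS = {
    "q2_table": 0.682,
    "q2_text": 0.628,
    "onc": 1,
    "r2": 0.928,
    "see": 0.160,
    "f_value": 12.194,
    "contributions_printed": {"S": 0.193, "E": 0.194, "H": 0.331, "D": 0.279,
                              "A": 0.218},
}


# ---------------------------------------------------------------------------
# Contour maps


@dataclass
class FieldContours:
    favored_points: np.ndarray  # grid point indices
    disfavored_points: np.ndarray
    upper_level: float
    lower_level: float


@dataclass
class ContourSet:
    per_field: dict[str, FieldContours] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, fc in self.per_field.items():
            if np.intersect1d(fc.favored_points, fc.disfavored_points).size:
                raise ValueError(f"field {label}: favored/disfavored overlap")


def contour_maps(
    model: PlsQsarModel,
    matrix: FieldMatrix,
    upper_pct: float = 80.0,
    lower_pct: float = 20.0,
) -> ContourSet:
    """Favored/disfavored grid points per field: coefficient·stdev products
    above the upper / below the lower percentile of that field's active
    columns.  Fields with fewer than 2 active columns yield empty contours
    with a warning."""
    if not lower_pct < upper_pct:
        raise ValueError("lower_pct must be < upper_pct")
    out: dict[str, FieldContours] = {}
    active_cols = np.where(matrix.active_mask)[0]
    prod = model.coefficients * model.column_sd
    for label in matrix.field_labels:
        block = matrix.field_block(label)
        in_field = (active_cols >= block.start) & (active_cols < block.stop)
        if in_field.sum() < 2:
            warnings.warn(f"field {label}: fewer than 2 active columns; "
                          "empty contours", stacklevel=2)
            out[label] = FieldContours(
                favored_points=np.array([], dtype=int),
                disfavored_points=np.array([], dtype=int),
                upper_level=float("nan"),
                lower_level=float("nan"),
            )
            continue
        vals = prod[in_field]
        pts = np.array([matrix.column_point(c) for c in active_cols[in_field]])
        hi = float(np.percentile(vals, upper_pct))
        lo = float(np.percentile(vals, lower_pct))
        out[label] = FieldContours(
            favored_points=pts[vals > hi],
            disfavored_points=pts[vals < lo],
            upper_level=hi,
            lower_level=lo,
        )
    return ContourSet(per_field=out)


def write_dx(grid: FieldGrid, values: np.ndarray, path: str | Path) -> None:
    """Write a scalar grid in OpenDX format (z varying fastest)."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size != grid.n_points:
        raise ValueError("value count does not match grid")
    nx, ny, nz = grid.counts
    ox, oy, oz = grid.origin
    s = grid.spacing
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
        f"delta {s:.6f} 0.000000 0.000000",
        f"delta 0.000000 {s:.6f} 0.000000",
        f"delta 0.000000 0.000000 {s:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {values.size} data follows",
    ]
    for i in range(0, values.size, 3):
        lines.append(" ".join(f"{v:.6e}" for v in values[i : i + 3]))
    lines += [
        'attribute "dep" string "positions"',
        'object "field" class field',
        'component "positions" value 1',
        'component "connections" value 2',
        'component "data" value 3',
        "",
    ]
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def export_contours(
    model: PlsQsarModel,
    matrix: FieldMatrix,
    out_dir: str | Path,
    upper_pct: float = 80.0,
    lower_pct: float = 20.0,
) -> list[Path]:
    """Export per-field favored/disfavored indicator grids as OpenDX files."""
    cs = contour_maps(model, matrix, upper_pct, lower_pct)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for label, fc in cs.per_field.items():
        for sign, pts in (("favored", fc.favored_points),
                          ("disfavored", fc.disfavored_points)):
            vals = np.zeros(matrix.grid.n_points)
            vals[pts] = 1.0
            p = out_dir / f"comsia_{label}_{sign}.dx"
            write_dx(matrix.grid, vals, p)
            written.append(p)
    return written
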