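"""Quasi-static volume conduction in a layered forearm and a 2D disc.

The tissue block is a rectangular box: skin, fat and muscle layers stacked
in depth (z, positive downward from the skin surface), with muscle
conductivity and permittivity anisotropic (along-fibre x vs across y, z).
At the stimulation frequency omega the complex continuity equation

    div( (sigma + j omega eps0 epsr) grad V ) = 0

is discretised by a cell-centred finite-volume scheme on a tensor-product
grid (uniform in x and y, arbitrarily graded in z) and solved with a sparse
direct factorisation.  Gel electrodes couple to the skin through a
distributed electrode-skin interface (ESI): a constant phase element (CPE)
in parallel with a charge-transfer resistance, per-area admittance

    Y_esi = 1/R_p + (j omega)^alpha / K.

Each electrode's gel is a floating equipotential unknown; active electrodes
carry a prescribed total current, inactive ones zero.  The two carrier
pairs are solved independently and superposed, mirroring isolated current
sources.  Activating functions A = |d2V/dx2| on the nerve plane feed the
time-over-threshold (TOT) map.

A separate 2D disc model compares 4-electrode interference (TIS) with
2-electrode premodulated AM stimulation in scaled units: TIS is bimodal
(tonic shells around the electrodes, a phasic hotspot between the pairs)
while the 2-electrode arrangement modulates every point fully (monomodal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .tot_analysis import tot_closed_form_array, classify_region

__all__ = [
    "TissueLayer",
    "TissueModel",
    "ElectrodePatch",
    "ElectrodeSetup",
    "FieldSolution",
    "default_crossed_pairs",
    "graded_edges",
    "solve_pair",
    "activating_amplitude",
    "tot_map",
    "disc_compare",
    "DiscResult",
    "write_vtk_structured_grid",
]

EPS0 = 8.8541878128e-12  # F/m

# Tissue parameters at 2.5 kHz (conductivity S/m, relative permittivity);
# muscle is anisotropic: x = along fibres, y/z = across.
DEFAULT_MUSCLE_SIGMA = (0.6, 0.35, 0.35)
DEFAULT_MUSCLE_EPSR = (1.5e5, 1.0e5, 1.0e5)
DEFAULT_FAT_SIGMA = 0.024
DEFAULT_FAT_EPSR = 3000.0
DEFAULT_SKIN_SIGMA = 0.0015
DEFAULT_SKIN_EPSR = 40000.0
DEFAULT_GEL_SIGMA = 0.27

# ESI defaults (area-normalised, MOhm cm^2 family of units)
DEFAULT_ESI_K = 35.0  # MOhm s^-alpha cm^2
DEFAULT_ESI_ALPHA = 0.9
DEFAULT_ESI_RP = 4.7  # MOhm cm^2


@dataclass(frozen=True)
class TissueLayer:
    """One horizontal layer: per-axis complex admittivity ingredients."""

    name: str
    thickness_mm: float  # np.inf for the bottom layer (fills the domain)
    sigma: tuple  # (x, y, z) S/m
    epsr: tuple  # (x, y, z) relative permittivity

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma):
            raise ValueError(f"layer {self.name}: conductivities must be positive")
        if any(e < 0 for e in self.epsr):
            raise ValueError(f"layer {self.name}: permittivities must be >= 0")


def _iso(v: float) -> tuple:
    return (v, v, v)


@dataclass(frozen=True)
class TissueModel:
    """Layered block geometry with its grid resolution and frequency."""

    extent_x_mm: float = 160.0
    extent_y_mm: float = 160.0
    extent_z_mm: float = 60.0
    layers: tuple = (
        TissueLayer("skin", 1.5, _iso(DEFAULT_SKIN_SIGMA), _iso(DEFAULT_SKIN_EPSR)),
        TissueLayer("fat", 5.0, _iso(DEFAULT_FAT_SIGMA), _iso(DEFAULT_FAT_EPSR)),
        TissueLayer("muscle", np.inf, DEFAULT_MUSCLE_SIGMA, DEFAULT_MUSCLE_EPSR),
    )
    frequency_hz: float = 2500.0
    nerve_depth_mm: float = 10.0  # nerve runs along x at y = 0, this depth
    dx_mm: float = 4.0  # uniform horizontal grid step
    nz_per_layer: tuple = (3, 4, 0)  # 0 => graded fill for the bottom layer
    muscle_dz_min_mm: float = 1.0
    muscle_dz_max_mm: float = 6.0
    # optional explicit cell-edge overrides (mm); enable locally refined
    # lateral grids for oracle comparisons
    x_edges_override_mm: tuple | None = None
    y_edges_override_mm: tuple | None = None
    z_edges_override_mm: tuple | None = None

    def __post_init__(self) -> None:
        if self.extent_x_mm <= 0 or self.extent_y_mm <= 0 or self.extent_z_mm <= 0:
            raise ValueError("domain extents must be positive")
        if self.frequency_hz < 0:
            raise ValueError("frequency must be non-negative")
        finite = [l.thickness_mm for l in self.layers[:-1]]
        if any(not np.isfinite(t) or t <= 0 for t in finite):
            raise ValueError("all but the last layer need finite positive thickness")
        if sum(finite) >= self.extent_z_mm:
            raise ValueError("finite layers exceed the domain depth")
        if not (0 < self.nerve_depth_mm < self.extent_z_mm):
            raise ValueError("nerve depth must lie inside the domain")
        mus = self.layers[-1]
        if mus.sigma[0] < mus.sigma[1]:
            raise ValueError(
                "muscle anisotropy ratio along/across must be >= 1"
            )

    # grids -----------------------------------------------------------------
    def z_edges_mm(self) -> np.ndarray:
        """Depth cell edges: fixed per-layer counts, graded bottom layer."""
        if self.z_edges_override_mm is not None:
            return np.asarray(self.z_edges_override_mm, dtype=float)
        edges = [0.0]
        for layer, n in zip(self.layers[:-1], self.nz_per_layer):
            if n < 2:
                raise ValueError(
                    f"layer {layer.name} must be resolved by >= 2 cells in depth"
                )
            t = layer.thickness_mm
            edges.extend(edges[-1] + t * (i + 1) / n for i in range(n))
        z0 = edges[-1]
        remaining = self.extent_z_mm - z0
        # geometric grading from muscle_dz_min to muscle_dz_max
        dz = []
        cur = self.muscle_dz_min_mm
        total = 0.0
        while total + cur < remaining:
            dz.append(cur)
            total += cur
            cur = min(cur * 1.3, self.muscle_dz_max_mm)
        dz.append(remaining - total)
        if len(dz) < 2:
            raise ValueError("bottom layer must be resolved by >= 2 cells in depth")
        edges.extend(z0 + np.cumsum(dz))
        return np.asarray(edges)

    def x_edges_mm(self) -> np.ndarray:
        if self.x_edges_override_mm is not None:
            return np.asarray(self.x_edges_override_mm, dtype=float)
        n = max(4, int(round(self.extent_x_mm / self.dx_mm)))
        return np.linspace(-self.extent_x_mm / 2, self.extent_x_mm / 2, n + 1)

    def y_edges_mm(self) -> np.ndarray:
        if self.y_edges_override_mm is not None:
            return np.asarray(self.y_edges_override_mm, dtype=float)
        n = max(4, int(round(self.extent_y_mm / self.dx_mm)))
        return np.linspace(-self.extent_y_mm / 2, self.extent_y_mm / 2, n + 1)

    def layer_of_depth(self, z_mm: float) -> TissueLayer:
        z0 = 0.0
        for layer in self.layers[:-1]:
            z0 += layer.thickness_mm
            if z_mm < z0:
                return layer
        return self.layers[-1]

    def admittivity(self, z_mm: float) -> np.ndarray:
        """Complex per-axis admittivity sigma + j w eps0 epsr at depth z."""
        layer = self.layer_of_depth(z_mm)
        w = 2 * np.pi * self.frequency_hz
        return np.array(
            [s + 1j * w * EPS0 * e for s, e in zip(layer.sigma, layer.epsr)]
        )


def graded_edges(
    half_extent: float,
    fine_halfwidth: float,
    h_fine: float,
    h_coarse: float,
    center: float = 0.0,
    ratio: float = 1.3,
) -> tuple:
    """Symmetric 1D cell edges: uniform ``h_fine`` inside
    ``[center - fine_halfwidth, center + fine_halfwidth]``, geometrically
    grown to ``h_coarse`` toward ``center +/- half_extent``."""
    if not (0 < h_fine <= h_coarse) or fine_halfwidth <= 0:
        raise ValueError("need 0 < h_fine <= h_coarse and fine_halfwidth > 0")
    n_fine = max(1, int(round(2 * fine_halfwidth / h_fine)))
    fine = np.linspace(center - fine_halfwidth, center + fine_halfwidth, n_fine + 1)
    right = [fine[-1]]
    h = h_fine
    while right[-1] < center + half_extent:
        h = min(h * ratio, h_coarse)
        right.append(min(right[-1] + h, center + half_extent))
    if right[-1] - right[-2] < 0.3 * h_fine:
        right.pop(-2)
    left = [fine[0]]
    h = h_fine
    while left[-1] > center - half_extent:
        h = min(h * ratio, h_coarse)
        left.append(max(left[-1] - h, center - half_extent))
    if left[-2] - left[-1] < 0.3 * h_fine:
        left.pop(-2)
    return tuple(np.concatenate([left[:0:-1], fine, right[1:]]))


@dataclass(frozen=True)
class ElectrodePatch:
    """Square surface electrode patch."""

    center_x_mm: float
    center_y_mm: float
    size_mm: float = 20.0
    pair: int = 1  # 1 or 2
    polarity: int = +1  # +1 source, -1 sink

    def __post_init__(self) -> None:
        if self.size_mm <= 0:
            raise ValueError("electrode size must be positive")
        if self.pair not in (1, 2):
            raise ValueError("pair id must be 1 or 2")
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")

    def covers(self, x_mm: float, y_mm: float) -> bool:
        return (
            abs(x_mm - self.center_x_mm) <= self.size_mm / 2
            and abs(y_mm - self.center_y_mm) <= self.size_mm / 2
        )

    def overlaps(self, other: "ElectrodePatch") -> bool:
        return (
            abs(self.center_x_mm - other.center_x_mm)
            < (self.size_mm + other.size_mm) / 2
            and abs(self.center_y_mm - other.center_y_mm)
            < (self.size_mm + other.size_mm) / 2
        )


def default_crossed_pairs(
    half_span_x_mm: float = 30.0, half_span_y_mm: float = 20.0, size_mm: float = 20.0
) -> tuple:
    """Two electrode pairs crossing obliquely over a nerve along y = 0.

    Pair 1 runs lower-left to upper-right, pair 2 upper-left to lower-right,
    so the midline between the pairs lies along the nerve.
    """
    return (
        ElectrodePatch(-half_span_x_mm, -half_span_y_mm, size_mm, pair=1, polarity=+1),
        ElectrodePatch(+half_span_x_mm, +half_span_y_mm, size_mm, pair=1, polarity=-1),
        ElectrodePatch(-half_span_x_mm, +half_span_y_mm, size_mm, pair=2, polarity=+1),
        ElectrodePatch(+half_span_x_mm, -half_span_y_mm, size_mm, pair=2, polarity=-1),
    )


@dataclass(frozen=True)
class ElectrodeSetup:
    """Electrode montage, ESI parameters and pair currents."""

    patches: tuple = field(default_factory=default_crossed_pairs)
    esi_k: float = DEFAULT_ESI_K  # MOhm s^-alpha cm^2
    esi_alpha: float = DEFAULT_ESI_ALPHA
    esi_rp: float = DEFAULT_ESI_RP  # MOhm cm^2
    current_1_ma: float = 5.0
    current_2_ma: float = 5.0
    f1_hz: float = 2500.0
    f2_hz: float = 2501.0

    def __post_init__(self) -> None:
        if self.esi_k <= 0 or self.esi_rp <= 0:
            raise ValueError("ESI parameters must be positive")
        if not (0 < self.esi_alpha <= 1):
            raise ValueError("ESI alpha must lie in (0, 1]")
        for pair in (1, 2):
            pols = sorted(p.polarity for p in self.patches if p.pair == pair)
            if pols and pols != [-1, +1]:
                raise ValueError(
                    f"pair {pair} must have exactly one + and one - patch"
                )
        for i, a in enumerate(self.patches):
            for b in self.patches[i + 1 :]:
                if a.overlaps(b):
                    raise ValueError("electrode patches must not overlap")

    def pair_current_ma(self, pair: int) -> float:
        return self.current_1_ma if pair == 1 else self.current_2_ma

    def esi_admittance_per_m2(self, frequency_hz: float) -> complex:
        """ESI per-area admittance 1/R_p + (j w)^alpha / K in S/m^2."""
        w = 2 * np.pi * frequency_hz
        rp = self.esi_rp * 1e6 * 1e-4  # MOhm cm^2 -> Ohm m^2
        k = self.esi_k * 1e6 * 1e-4  # MOhm s^-alpha cm^2 -> Ohm s^-alpha m^2
        return 1.0 / rp + (1j * w) ** self.esi_alpha / k


@dataclass
class FieldSolution:
    """Complex potential on the grid for one (or both) active pairs."""

    tissue: TissueModel
    setup: ElectrodeSetup
    x_centers_mm: np.ndarray
    y_centers_mm: np.ndarray
    z_centers_mm: np.ndarray
    potential: np.ndarray  # complex, shape (nx, ny, nz), volts
    gel_potentials: np.ndarray  # complex, one per patch
    electrode_currents_ma: np.ndarray  # recomputed from the solution
    active_pair: int | None  # None = all pairs active
    residual: float


# ---------------------------------------------------------------------------
# 3D layered solver


def _assemble(tissue: TissueModel, setup: ElectrodeSetup, currents_ma: dict):
    """Build the finite-volume system; returns solution components."""
    xe = tissue.x_edges_mm() * 1e-3
    ye = tissue.y_edges_mm() * 1e-3
    ze = tissue.z_edges_mm() * 1e-3
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    zc = 0.5 * (ze[:-1] + ze[1:])
    nx, ny, nz = len(xc), len(yc), len(zc)
    n = nx * ny * nz

    def idx(i, j, k):
        return (i * ny + j) * nz + k

    # per-cell admittivity (complex per-axis)
    adm = np.empty((nz, 3), dtype=complex)
    for k in range(nz):
        adm[k] = tissue.admittivity(zc[k] * 1e3)
    dx = np.diff(xe)
    dy = np.diff(ye)
    dz = np.diff(ze)

    rows, cols, vals = [], [], []
    diag = np.zeros(n, dtype=complex)

    def add(i1, i2, g):
        rows.append(i1)
        cols.append(i2)
        vals.append(-g)
        diag[i1] += g

    # x faces
    for i in range(nx - 1):
        d = xc[i + 1] - xc[i]
        for j in range(ny):
            for k in range(nz):
                g = adm[k, 0] * dy[j] * dz[k] / d
                a, b = idx(i, j, k), idx(i + 1, j, k)
                add(a, b, g)
                add(b, a, g)
    # y faces
    for j in range(ny - 1):
        d = yc[j + 1] - yc[j]
        for i in range(nx):
            for k in range(nz):
                g = adm[k, 1] * dx[i] * dz[k] / d
                a, b = idx(i, j, k), idx(i, j + 1, k)
                add(a, b, g)
                add(b, a, g)
    # z faces: harmonic mean across layer interfaces
    for k in range(nz - 1):
        s1, s2 = adm[k, 2], adm[k + 1, 2]
        # series of the two half-cells
        g_unit = 1.0 / (dz[k] / (2 * s1) + dz[k + 1] / (2 * s2))
        for i in range(nx):
            for j in range(ny):
                g = g_unit * dx[i] * dy[j]
                a, b = idx(i, j, k), idx(i, j, k + 1)
                add(a, b, g)
                add(b, a, g)

    # electrode coupling through the ESI on the top surface (k = 0):
    # half-cell bulk path in series with the ESI film, per covered cell
    y_esi = setup.esi_admittance_per_m2(tissue.frequency_hz)
    n_pat = len(setup.patches)
    gel_rows = []  # per patch: list of (cell index, face conductance)
    for p_i, patch in enumerate(setup.patches):
        faces = []
        for i in range(nx):
            for j in range(ny):
                if patch.covers(xc[i] * 1e3, yc[j] * 1e3):
                    area = dx[i] * dy[j]
                    g_half = adm[0, 2] * area / (dz[0] / 2)
                    g_esi = y_esi * area
                    faces.append((idx(i, j, 0), 1.0 / (1.0 / g_half + 1.0 / g_esi)))
        gel_rows.append(faces)
        if not gel_rows[p_i]:
            raise ValueError(
                f"electrode patch {p_i} covers no grid cells; refine dx"
            )

    # augmented system: cells then gel potentials
    N = n + n_pat
    for p_i, faces in enumerate(gel_rows):
        gi = n + p_i
        for cell, g in faces:
            rows.append(cell)
            cols.append(gi)
            vals.append(-g)
            diag[cell] += g
            rows.append(gi)
            cols.append(cell)
            vals.append(-g)

    rows.extend(range(n))
    cols.extend(range(n))
    vals.extend(diag)
    for p_i, faces in enumerate(gel_rows):
        gi = n + p_i
        rows.append(gi)
        cols.append(gi)
        vals.append(sum(g for _, g in faces))

    A = sp.csr_matrix(
        (np.asarray(vals, dtype=complex), (rows, cols)), shape=(N, N)
    )
    rhs = np.zeros(N, dtype=complex)
    for p_i, patch in enumerate(setup.patches):
        i_ma = currents_ma.get(p_i, 0.0)
        rhs[n + p_i] = patch.polarity * i_ma * 1e-3  # A into the gel

    # pin the potential at one corner cell to remove the constant nullspace
    pin = 0
    A = A.tolil()
    A.rows[pin] = [pin]
    A.data[pin] = [1.0]
    rhs[pin] = 0.0
    A = A.tocsr()

    imag_max = np.abs(A.data.imag).max() if A.nnz else 0.0
    if imag_max > 0:
        sol = spla.spsolve(A, rhs)
    else:
        sol = spla.spsolve(A.real, rhs.real).astype(complex)
    residual = float(np.linalg.norm(A @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))

    V = sol[:n].reshape(nx, ny, nz)
    gels = sol[n:]
    # recompute electrode currents from the solution (conservation check)
    currents = np.zeros(n_pat, dtype=complex)
    for p_i, faces in enumerate(gel_rows):
        currents[p_i] = sum(
            g * (gels[p_i] - sol[cell]) for cell, g in faces
        )
    return xc * 1e3, yc * 1e3, zc * 1e3, V, gels, currents * 1e3, residual


def solve_pair(
    tissue: TissueModel, setup: ElectrodeSetup, pair: int | None
) -> FieldSolution:
    """Solve with one electrode pair active (or both, ``pair=None``).

    The inactive pair's electrodes stay in place as floating equipotential
    gels carrying zero net current, mirroring isolated current sources.
    """
    currents = {}
    for p_i, patch in enumerate(setup.patches):
        if pair is None or patch.pair == pair:
            currents[p_i] = setup.pair_current_ma(patch.pair)
    if not currents:
        raise ValueError(f"no electrodes belong to pair {pair}")
    xc, yc, zc, V, gels, i_ma, res = _assemble(tissue, setup, currents)
    sol = FieldSolution(
        tissue=tissue,
        setup=setup,
        x_centers_mm=xc,
        y_centers_mm=yc,
        z_centers_mm=zc,
        potential=V,
        gel_potentials=gels,
        electrode_currents_ma=i_ma,
        active_pair=pair,
        residual=res,
    )
    _check_currents(sol, currents)
    return sol


def _check_currents(sol: FieldSolution, prescribed: dict) -> None:
    for p_i, patch in enumerate(sol.setup.patches):
        want = patch.polarity * prescribed.get(p_i, 0.0)
        got = sol.electrode_currents_ma[p_i].real
        if want != 0 and abs(got - want) > 1e-3 * abs(want):
            raise RuntimeError(
                f"electrode {p_i}: current {got:.6g} mA deviates from the "
                f"prescribed {want:.6g} mA by more than 0.1%"
            )


def activating_amplitude(sol: FieldSolution, nerve_depth_mm: float | None = None):
    """|d2V/dx2| on the nerve plane, V/m^2 (per active pair's solution).

    Returns ``(x_mm, y_mm, amplitude)`` where amplitude has shape
    (nx - 2, ny): the modulus of the central second difference of the
    complex potential along the fibre direction x.
    """
    if nerve_depth_mm is None:
        nerve_depth_mm = sol.tissue.nerve_depth_mm
    zc = sol.z_centers_mm
    if not (zc[0] <= nerve_depth_mm <= zc[-1]):
        raise ValueError("nerve plane lies outside the grid")
    finite = sum(l.thickness_mm for l in sol.tissue.layers[:-1])
    if nerve_depth_mm <= finite:
        raise ValueError("nerve plane must lie inside the bottom (muscle) layer")
    k = int(np.argmin(np.abs(zc - nerve_depth_mm)))
    V = sol.potential[:, :, k]
    x_m = sol.x_centers_mm * 1e-3
    hm = (x_m[1:-1] - x_m[:-2])[:, None]
    hp = (x_m[2:] - x_m[1:-1])[:, None]
    d2 = 2.0 * ((V[2:, :] - V[1:-1, :]) / hp - (V[1:-1, :] - V[:-2, :]) / hm) / (
        hp + hm
    )
    return sol.x_centers_mm[1:-1], sol.y_centers_mm, np.abs(d2)


def tot_map(a1: np.ndarray, a2: np.ndarray, a_threshold: float = 1000.0):
    """Element-wise TOT and region labels from two activating maps.

    ``a_threshold`` defaults to 1000 V/m^2, the activation threshold of a
    2.5 kHz carrier calibrated from measured current thresholds.
    """
    tot = tot_closed_form_array(a1, a2, a_threshold)
    labels = np.empty(tot.shape, dtype=object)
    flat = tot.ravel()
    lab = labels.ravel()
    for i in range(flat.size):
        lab[i] = classify_region(float(flat[i]))
    return tot, labels


# ---------------------------------------------------------------------------
# 2D disc comparison: TIS (4 electrodes) vs premodulated AM (2 electrodes)


@dataclass
class DiscResult:
    """Scaled-field maps on the disc (polar grid, unit thickness).

    ``e_scaled_*`` hold the dimensionless scaled field Ebar = E sigma d / I:
    envelope maximum, envelope minimum (unmodulated floor) and modulation
    index per cell.  ``r_mm``/``theta`` give the cell-centre polar grid.
    """

    mode: str
    r: np.ndarray  # cell-centre radii, units of the diameter d
    theta: np.ndarray
    e_scaled_max: np.ndarray  # (nr, ntheta)
    e_scaled_min: np.ndarray
    modulation_index: np.ndarray
    center_envelope: float  # scaled envelope amplitude at the disc centre


def _disc_solve(nr: int, nth: int, sources: list) -> np.ndarray:
    """FV Laplace solve on the unit disc, insulated rim except injections.

    ``sources`` is a list of (theta, current) line injections on the rim.
    Returns the potential per unit (sigma * thickness), radius normalised
    to 1/2 (unit diameter).
    """
    R = 0.5
    dr = R / nr
    dth = 2 * np.pi / nth
    rc = (np.arange(nr) + 0.5) * dr
    n = nr * nth

    def idx(i, j):
        return i * nth + (j % nth)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)

    def add(i1, i2, g):
        rows.append(i1)
        cols.append(i2)
        vals.append(-g)
        diag[i1] += g

    for i in range(nr):
        for j in range(nth):
            a = idx(i, j)
            # radial neighbour outward
            if i < nr - 1:
                rf = (i + 1) * dr
                g = rf * dth / dr
                add(a, idx(i + 1, j), g)
            # angular neighbours
            g = dr / (rc[i] * dth)
            add(a, idx(i, j + 1), g)
            add(a, idx(i, j - 1), g)
    # symmetric: add the inward radial couplings (mirror of outward)
    for i in range(1, nr):
        for j in range(nth):
            rf = i * dr
            g = rf * dth / dr
            add(idx(i, j), idx(i - 1, j), g)

    rows.extend(range(n))
    cols.extend(range(n))
    vals.extend(diag)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    rhs = np.zeros(n)
    for theta, cur in sources:
        j = int(np.floor((theta % (2 * np.pi)) / dth))
        rhs[idx(nr - 1, j)] += cur
    # pin one cell
    A = A.tolil()
    A.rows[0] = [0]
    A.data[0] = [1.0]
    rhs[0] = 0.0
    A = A.tocsr()
    sol = spla.spsolve(A, rhs)
    return sol.reshape(nr, nth), rc, dr, dth


def _disc_field(V: np.ndarray, rc, dr, dth):
    """Cell-centre E = -grad V in Cartesian components (Er, Etheta mapped)."""
    nr, nth = V.shape
    Er = np.zeros((nr, nth))
    Et = np.zeros((nr, nth))
    # radial derivative (one-sided at both rims)
    Er[1:-1] = -(V[2:] - V[:-2]) / (2 * dr)
    Er[0] = -(V[1] - V[0]) / dr
    Er[-1] = -(V[-1] - V[-2]) / dr
    Vp = np.roll(V, -1, axis=1)
    Vm = np.roll(V, 1, axis=1)
    Et[:] = -(Vp - Vm) / (2 * dth) / rc[:, None]
    th = (np.arange(nth) + 0.5) * dth
    Ex = Er * np.cos(th)[None, :] - Et * np.sin(th)[None, :]
    Ey = Er * np.sin(th)[None, :] + Et * np.cos(th)[None, :]
    return Ex, Ey


# electrode angles: pair 1 on the left (135, 225 deg), pair 2 on the right
# (45, 315 deg); the AM mode reuses pair 2's positions
_TIS_PAIRS = {
    1: (3 * np.pi / 4, 5 * np.pi / 4),
    2: (np.pi / 4, 7 * np.pi / 4),
}


def disc_compare(
    mode: str,
    per_channel_current: float = 1.0,
    nr: int = 60,
    nth: int = 240,
    diameter: float = 1.0,
    conductivity: float = 1.0,
) -> DiscResult:
    """Solve the disc for one stimulation mode and report scaled fields.

    ``tis_4_electrode``: each carrier drives its own diametral pair; the
    envelope extremes at a point are |E1 +/- E2| over the beat.
    ``am_2_electrode``: the premodulated sum of both carriers (peak twice
    the per-channel amplitude) drives one pair; the envelope swings between
    2|E| and 0 everywhere, so the modulation index is 1 at every point.

    Fields are returned as Ebar = E * sigma * d / I per unit thickness,
    which depends only on the geometry (I, sigma, d scale out exactly).
    """
    if mode not in ("tis_4_electrode", "am_2_electrode"):
        raise ValueError("mode must be 'tis_4_electrode' or 'am_2_electrode'")
    I = per_channel_current
    # solve in normalised units (sigma = 1, d = 1, I = 1): Ebar is exactly
    # the normalised field, independent of the physical values
    fields = []
    if mode == "tis_4_electrode":
        for pair in (1, 2):
            a, b = _TIS_PAIRS[pair]
            V, rc, dr, dth = _disc_solve(nr, nth, [(a, +1.0), (b, -1.0)])
            fields.append(_disc_field(V, rc, dr, dth))
        (e1x, e1y), (e2x, e2y) = fields
        e_plus = np.hypot(e1x + e2x, e1y + e2y)
        e_minus = np.hypot(e1x - e2x, e1y - e2y)
        e_max = np.maximum(e_plus, e_minus)
        e_min = np.minimum(e_plus, e_minus)
    else:
        a, b = _TIS_PAIRS[2]
        V, rc, dr, dth = _disc_solve(nr, nth, [(a, +1.0), (b, -1.0)])
        ex, ey = _disc_field(V, rc, dr, dth)
        e_max = 2.0 * np.hypot(ex, ey)  # premodulated peak = 2 I
        e_min = np.zeros_like(e_max)

    with np.errstate(invalid="ignore", divide="ignore"):
        mi = np.where(e_max + e_min > 0, (e_max - e_min) / (e_max + e_min), 0.0)

    nth_ = e_max.shape[1]
    th = (np.arange(nth_) + 0.5) * (2 * np.pi / nth_)
    # centre value: average the innermost ring (odd components cancel)
    if mode == "tis_4_electrode":
        c1x, c1y = fields[0][0][0].mean(), fields[0][1][0].mean()
        c2x, c2y = fields[1][0][0].mean(), fields[1][1][0].mean()
        center = float(np.hypot(c1x + c2x, c1y + c2y))
    else:
        center = float(2.0 * np.hypot(ex[0].mean(), ey[0].mean()))
    return DiscResult(
        mode=mode,
        r=rc,
        theta=th,
        e_scaled_max=e_max,
        e_scaled_min=e_min,
        modulation_index=mi,
        center_envelope=center,
    )


# ---------------------------------------------------------------------------
# export


def write_vtk_structured_grid(sol: FieldSolution, path) -> None:
    """Write |V| and Re/Im(V) as a legacy ASCII VTK structured grid."""
    x = sol.x_centers_mm
    y = sol.y_centers_mm
    z = sol.z_centers_mm
    nx, ny, nz = len(x), len(y), len(z)
    V = sol.potential
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("tiskit potential field (mm, V)\n")
        fh.write("ASCII\nDATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"POINTS {nx * ny * nz} float\n")
        for k in range(nz):
            for j in range(ny):
                for i in range(nx):
                    fh.write(f"{x[i]:.4f} {y[j]:.4f} {z[k]:.4f}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in (
            ("V_abs", np.abs(V)),
            ("V_re", V.real),
            ("V_im", V.imag),
        ):
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            for k in range(nz):
                for j in range(ny):
                    for i in range(nx):
                        fh.write(f"{arr[i, j, k]:.6e}\n")
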