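"""Monte Carlo photon transport for fiber-probe diffuse reflectance.

A homogeneous semi-infinite medium (z > 0) is illuminated through the face of
a multi-fiber probe in contact with the surface.  Photons are launched
uniformly over the illumination core within the fiber NA, propagate with
Henyey-Greenstein scattering, and are counted when they exit inside a
collection fiber footprint within the collection NA.  Absorption is applied
as continuous weight attenuation exp(-mua * pathlength), which permits a
single absorption-free *baseline* simulation to be rescaled to arbitrary
(mua, mus') by pathlength similarity -- the fast, scalable strategy used
instead of re-running the random walk per wavelength.

Scaling model: changing mus' by a factor k rescales every stored trajectory
displacement and pathlength by 1/k about its own launch point (the launch
optics are fixed hardware and do not scale); absorption is then applied to
the rescaled pathlength.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .spectra import OpticalProperties, WavelengthGrid

# ---------------------------------------------------------------------------
# configuration dataclasses


@dataclass(frozen=True)
class ProbeGeometry:
    """Contact probe: 19-fiber illumination core ringed by collection fibers.

    All lengths in cm.  The four collection fibers sit 90 degrees apart at a
    common offset from the probe axis; source-detector separations (fiber
    center to fiber center) must stay inside the 0.23-1.10 mm span of the
    instrument.
    """

    illum_core_radius_cm: float = 0.05
    fiber_radius_cm: float = 0.01
    collection_offset_cm: float = 0.065
    n_collection: int = 4
    na: float = 0.22
    n_tissue: float = 1.37
    n_ext: float = 1.45

    def __post_init__(self):
        if not (0.0 < self.na < 1.0):
            raise ValueError("NA must be in (0, 1)")
        if self.fiber_radius_cm <= 0 or self.illum_core_radius_cm <= 0:
            raise ValueError("fiber dimensions must be positive")
        lo, hi = self.separation_span_mm
        if lo < 0.23 - 1e-9 or hi > 1.10 + 1e-9:
            raise ValueError(
                f"source-detector separations {lo:.3f}-{hi:.3f} mm outside "
                "the 0.23-1.10 mm instrument span")

    @property
    def separation_span_mm(self):
        """Range of illumination-fiber-center to collection-center distances."""
        r_centers = self.illum_core_radius_cm - self.fiber_radius_cm
        return (10.0 * (self.collection_offset_cm - r_centers),
                10.0 * (self.collection_offset_cm + r_centers))


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo run parameters."""

    photon_count: int = 200_000
    rng_seed: int = 7151
    g: float = 0.9
    max_path_cm: float = 60.0
    roulette_threshold: float = 1e-4
    roulette_survive: float = 0.1
    record_dmax_cm: float = 0.6
    # photons beyond these bounds cannot re-enter the sub-mm collection zone
    # with non-negligible weight; killing them is a variance-free speedup for
    # the probe tally (the total-reflectance tally undercounts accordingly)
    kill_depth_cm: float = 2.0
    kill_lateral_cm: float = 3.0

    def __post_init__(self):
        if self.photon_count < 1_000:
            raise ValueError("photon_count must be >= 1e3")
        if not (0.0 <= self.g < 1.0):
            raise ValueError("anisotropy g must be in [0, 1)")


@dataclass(frozen=True)
class Spectrum:
    """Diffuse reflectance per unit incident power on a wavelength grid."""

    grid: WavelengthGrid
    values: np.ndarray
    provenance: str = "simulated"  # simulated | calibrated-measurement | synthetic

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid),):
            raise ValueError("values must match the grid length")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("reflectance values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


# ---------------------------------------------------------------------------
# njit kernels


@njit(cache=True)
def _fresnel_r(n1, n2, cosi):
    """Unpolarized Fresnel reflection coefficient, incidence from medium 1."""
    sini = np.sqrt(max(0.0, 1.0 - cosi * cosi))
    sint = n1 * sini / n2
    if sint >= 1.0:
        return 1.0
    cost = np.sqrt(1.0 - sint * sint)
    rs = (n1 * cosi - n2 * cost) / (n1 * cosi + n2 * cost)
    rp = (n1 * cost - n2 * cosi) / (n1 * cost + n2 * cosi)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _hg_cos(g):
    """Sample the cosine of the Henyey-Greenstein scattering angle."""
    u = np.random.random()
    if g < 1e-6:
        return 2.0 * u - 1.0
    s = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - s * s) / (2.0 * g)


@njit(cache=True)
def _spin(ux, uy, uz, cost, phi):
    """Rotate direction (ux,uy,uz) by scattering angle (cost, phi)."""
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = np.cos(phi)
    sinp = np.sin(phi)
    if abs(uz) > 0.99999:
        nx = sint * cosp
        ny = sint * sinp
        nz = cost * (1.0 if uz >= 0 else -1.0)
    else:
        den = np.sqrt(1.0 - uz * uz)
        nx = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
        ny = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
        nz = -sint * cosp * den + uz * cost
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def _azimuth_fraction(r, offset, rho, n_fib):
    """Fraction of the azimuth at radius r covered by n_fib fibers of radius
    rho centered at distance ``offset`` from the axis (non-overlapping)."""
    if r < 1e-12:
        return 1.0 if offset <= rho else 0.0
    if abs(r - offset) >= rho:
        return 0.0
    c = (r * r + offset * offset - rho * rho) / (2.0 * r * offset)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return n_fib * np.arccos(c) / np.pi / 2.0 * 2.0


@njit(cache=True)
def _launch(src_r, sin_na_t):
    """Launch position on the source disc and direction within the NA cone."""
    rr = src_r * np.sqrt(np.random.random())
    th = 2.0 * np.pi * np.random.random()
    x0 = rr * np.cos(th)
    y0 = rr * np.sin(th)
    cos_min = np.sqrt(1.0 - sin_na_t * sin_na_t)
    uz = cos_min + (1.0 - cos_min) * np.random.random()
    s = np.sqrt(max(0.0, 1.0 - uz * uz))
    ph = 2.0 * np.pi * np.random.random()
    return x0, y0, s * np.cos(ph), s * np.sin(ph), uz


@njit(cache=True)
def _mc_walk(n_photons, seed, mus, g, mua, src_r, sin_na_t, n_t, n_ext,
             max_path, dmax, offset, rho, n_fib,
             rl_thresh, rl_survive, record, kill_depth, kill_lateral):
    """Shared random-walk kernel.

    With ``record`` true it stores absorption-free exit records for baseline
    scaling; absorption (``mua``) is always applied to the collection tally so
    the same kernel serves direct simulation.  Returns
    (r0, d, cospsi, path, weight, photon_idx, n_rec, collected_batch,
    total_exit_w, n_killed) where collected_batch holds 10 batch sums of the
    collected reflectance tally.
    """
    np.random.seed(seed)
    r0_a = np.empty(n_photons)
    d_a = np.empty(n_photons)
    cp_a = np.empty(n_photons)
    pl_a = np.empty(n_photons)
    w_a = np.empty(n_photons)
    idx_a = np.empty(n_photons, dtype=np.int64)
    n_rec = 0
    batch = np.zeros(10)
    batch_size = n_photons // 10
    total_exit_w = 0.0
    n_killed = 0
    for ip in range(n_photons):
        x0, y0, ux, uy, uz = _launch(src_r, sin_na_t)
        x = x0
        y = y0
        z = 0.0
        path = 0.0
        boost = 1.0
        alive = True
        while alive:
            step = -np.log(np.random.random() + 1e-300) / mus
            while step > 0.0:
                if uz < 0.0:
                    s_b = -z / uz
                else:
                    s_b = 1e30
                if s_b <= step:
                    x += ux * s_b
                    y += uy * s_b
                    z = 0.0
                    path += s_b
                    step -= s_b
                    cosi = -uz
                    if np.random.random() < _fresnel_r(n_t, n_ext, cosi):
                        uz = -uz  # internal reflection
                        continue
                    # exit
                    w_exit = boost * np.exp(-mua * path)
                    total_exit_w += w_exit
                    sini = np.sqrt(max(0.0, 1.0 - cosi * cosi))
                    if n_t * sini <= sin_na_t * n_t + 1e-12:
                        dx = x - x0
                        dy = y - y0
                        d = np.sqrt(dx * dx + dy * dy)
                        r_exit = np.sqrt(x * x + y * y)
                        p = _azimuth_fraction(r_exit, offset, rho, n_fib)
                        if p > 0.0:
                            ib = min(ip // max(batch_size, 1), 9)
                            batch[ib] += w_exit * p
                        if record and d <= dmax:
                            rl = np.sqrt(x0 * x0 + y0 * y0)
                            if d > 1e-12 and rl > 1e-12:
                                cpsi = (x0 * dx + y0 * dy) / (rl * d)
                            else:
                                cpsi = 0.0
                            r0_a[n_rec] = rl
                            d_a[n_rec] = d
                            cp_a[n_rec] = min(1.0, max(-1.0, cpsi))
                            pl_a[n_rec] = path
                            w_a[n_rec] = boost
                            idx_a[n_rec] = ip
                            n_rec += 1
                    alive = False
                    break
                x += ux * step
                y += uy * step
                z += uz * step
                path += step
                step = 0.0
            if not alive:
                break
            dxk = x - x0
            dyk = y - y0
            if (path > max_path or z > kill_depth
                    or dxk * dxk + dyk * dyk > kill_lateral * kill_lateral):
                n_killed += 1
                break
            w_cur = boost * np.exp(-mua * path)
            if w_cur < rl_thresh:
                if np.random.random() < rl_survive:
                    boost /= rl_survive
                else:
                    n_killed += 1
                    break
            cost = _hg_cos(g)
            phi = 2.0 * np.pi * np.random.random()
            ux, uy, uz = _spin(ux, uy, uz, cost, phi)
    return (r0_a[:n_rec], d_a[:n_rec], cp_a[:n_rec], pl_a[:n_rec],
            w_a[:n_rec], idx_a[:n_rec], n_rec, batch, total_exit_w, n_killed)


@njit(cache=True, fastmath=True)
def _scale_records(r0, d, cospsi, path, w, n_photons, mua_arr, scale_arr,
                   offset, rho, n_fib):
    """Rescale baseline exit records to target (mua, mus') per wavelength."""
    out = np.zeros(mua_arr.size)
    for j in range(mua_arr.size):
        s = scale_arr[j]
        mua = mua_arr[j]
        acc = 0.0
        for i in range(r0.size):
            ds = d[i] * s
            r = np.sqrt(r0[i] * r0[i] + ds * ds + 2.0 * r0[i] * ds * cospsi[i])
            p = _azimuth_fraction(r, offset, rho, n_fib)
            if p > 0.0:
                acc += w[i] * np.exp(-mua * path[i] * s) * p
        out[j] = acc / n_photons
    return out


@njit(cache=True)
def _scale_records_batched(r0, d, cospsi, path, w, idx, n_photons, mua,
                           scale, offset, rho, n_fib):
    """Single-wavelength rescaling with 10 photon-index batch sums."""
    batch = np.zeros(10)
    bsize = max(n_photons // 10, 1)
    for i in range(r0.size):
        ds = d[i] * scale
        r = np.sqrt(r0[i] * r0[i] + ds * ds + 2.0 * r0[i] * ds * cospsi[i])
        p = _azimuth_fraction(r, offset, rho, n_fib)
        if p > 0.0:
            ib = min(idx[i] // bsize, 9)
            batch[ib] += w[i] * np.exp(-mua * path[i] * scale) * p
    return batch


@njit(cache=True)
def _mc_radial(n_photons, seed, mus, g, mua, src_r, sin_na_t, n_t, n_ext,
               max_path, r_edges, kill_depth, kill_lateral):
    """Radial diffuse reflectance profile R(rho) per cm^2 per photon.

    All exiting photons are tallied regardless of exit angle -- this is the
    quantity diffusion theory predicts.
    """
    np.random.seed(seed)
    tally = np.zeros(r_edges.size - 1)
    for ip in range(n_photons):
        x0, y0, ux, uy, uz = _launch(src_r, sin_na_t)
        x = x0
        y = y0
        z = 0.0
        path = 0.0
        alive = True
        while alive:
            step = -np.log(np.random.random() + 1e-300) / mus
            while step > 0.0:
                s_b = -z / uz if uz < 0.0 else 1e30
                if s_b <= step:
                    x += ux * s_b
                    y += uy * s_b
                    z = 0.0
                    path += s_b
                    step -= s_b
                    cosi = -uz
                    if np.random.random() < _fresnel_r(n_t, n_ext, cosi):
                        uz = -uz
                        continue
                    r = np.sqrt(x * x + y * y)
                    for k in range(r_edges.size - 1):
                        if r_edges[k] <= r < r_edges[k + 1]:
                            tally[k] += np.exp(-mua * path)
                            break
                    alive = False
                    break
                x += ux * step
                y += uy * step
                z += uz * step
                path += step
                step = 0.0
            if not alive:
                break
            if (path > max_path or np.exp(-mua * path) < 1e-6
                    or z > kill_depth
                    or x * x + y * y > kill_lateral * kill_lateral):
                break
            cost = _hg_cos(g)
            phi = 2.0 * np.pi * np.random.random()
            ux, uy, uz = _spin(ux, uy, uz, cost, phi)
    areas = np.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2)
    return tally / areas / n_photons


# ---------------------------------------------------------------------------
# public API


#: validated mus' rescaling range relative to the baseline reference
SCALING_RANGE = (0.25, 4.0)


@dataclass
class BaselineSimulation:
    """Stored absorption-free exit records from one reference medium.

    Records are reproducible bit-identically from (geometry, config,
    reference properties, seed).  ``weight`` carries roulette boosts (unity
    in a pure baseline run); absorption enters only at rescaling time.
    """

    geometry: ProbeGeometry
    config: MCConfig
    mua_ref: float
    musp_ref: float
    r0: np.ndarray
    d: np.ndarray
    cospsi: np.ndarray
    path: np.ndarray
    weight: np.ndarray
    photon_idx: np.ndarray
    total_exit_weight: float
    n_killed: int

    @property
    def n_photons(self) -> int:
        return self.config.photon_count

    @property
    def n_records(self) -> int:
        return self.r0.size

    def collected_reflectance(self, mua: float | None = None) -> float:
        """Collected reflectance of the baseline medium itself (its own
        reference absorption applied post hoc unless overridden)."""
        mua = self.mua_ref if mua is None else mua
        return float(scale_reflectance(self, mua, self.musp_ref))

    def save(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for k in ("r0", "d", "cospsi", "path", "weight", "photon_idx"):
                f.create_dataset(k, data=getattr(self, k))
            f.attrs["header"] = json.dumps({
                "mua_ref": self.mua_ref, "musp_ref": self.musp_ref,
                "total_exit_weight": self.total_exit_weight,
                "n_killed": self.n_killed,
                "geometry": self.geometry.__dict__,
                "config": self.config.__dict__,
            })

    @classmethod
    def load(cls, path: str) -> "BaselineSimulation":
        import h5py

        with h5py.File(path, "r") as f:
            hdr = json.loads(f.attrs["header"])
            arrays = {k: f[k][:] for k in
                      ("r0", "d", "cospsi", "path", "weight", "photon_idx")}
        return cls(geometry=ProbeGeometry(**hdr["geometry"]),
                   config=MCConfig(**hdr["config"]),
                   mua_ref=hdr["mua_ref"], musp_ref=hdr["musp_ref"],
                   total_exit_weight=hdr["total_exit_weight"],
                   n_killed=hdr["n_killed"], **arrays)


def _check_props(mua: float, musp: float) -> None:
    if mua < 0:
        raise ValueError("mua must be non-negative")
    if musp <= 0:
        raise ValueError("mus' must be strictly positive")


def run_direct_mc(mua: float, musp: float, geom: ProbeGeometry, cfg: MCConfig,
                  return_se: bool = False):
    """Direct single-wavelength MC: collected probe reflectance in [0, 1].

    Standard error (10 batch means) is returned when ``return_se`` is set.
    """
    _check_props(mua, musp)
    mus = musp / (1.0 - cfg.g)
    out = _mc_walk(cfg.photon_count, cfg.rng_seed, mus, cfg.g, mua,
                   geom.illum_core_radius_cm, geom.na / geom.n_tissue,
                   geom.n_tissue, geom.n_ext, cfg.max_path_cm,
                   cfg.record_dmax_cm, geom.collection_offset_cm,
                   geom.fiber_radius_cm, geom.n_collection,
                   cfg.roulette_threshold, cfg.roulette_survive, False,
                   cfg.kill_depth_cm, cfg.kill_lateral_cm)
    batch = out[7]
    bsize = cfg.photon_count // 10
    means = batch / bsize
    refl = float(np.sum(batch) / cfg.photon_count)
    if not return_se:
        return refl
    se = float(np.std(means, ddof=1) / np.sqrt(10.0))
    return refl, se


def build_baseline(geom: ProbeGeometry, cfg: MCConfig, mua_ref: float = 0.1,
                   musp_ref: float = 6.68) -> BaselineSimulation:
    """Run the reference simulation and store per-photon exit records.

    The walk itself is absorption-free (absorption is applied post hoc at
    rescaling time); ``mua_ref`` only defines the medium the baseline's own
    collected reflectance refers to.
    """
    _check_props(mua_ref, musp_ref)
    mus = musp_ref / (1.0 - cfg.g)
    (r0, d, cp, pl, w, idx, n_rec, batch, tot_w, n_killed) = _mc_walk(
        cfg.photon_count, cfg.rng_seed, mus, cfg.g, 0.0,
        geom.illum_core_radius_cm, geom.na / geom.n_tissue,
        geom.n_tissue, geom.n_ext, cfg.max_path_cm, cfg.record_dmax_cm,
        geom.collection_offset_cm, geom.fiber_radius_cm, geom.n_collection,
        cfg.roulette_threshold, cfg.roulette_survive, True,
        cfg.kill_depth_cm, cfg.kill_lateral_cm)
    if n_rec == 0:
        raise RuntimeError("baseline collected no photons -- geometry or "
                           "configuration fault")
    return BaselineSimulation(geometry=geom, config=cfg, mua_ref=mua_ref,
                              musp_ref=musp_ref, r0=r0.copy(), d=d.copy(),
                              cospsi=cp.copy(), path=pl.copy(),
                              weight=w.copy(), photon_idx=idx.copy(),
                              total_exit_weight=tot_w, n_killed=n_killed)


def scale_reflectance(base: BaselineSimulation, mua, musp, strict: bool = True,
                      return_se: bool = False):
    """Rescale the baseline to target optical properties.

    ``mua``/``musp`` may be scalars or equal-length arrays (one value per
    wavelength).  With ``strict`` the mus' ratio must stay inside the
    validated 0.25-4x range of the baseline.
    """
    mua_arr = np.atleast_1d(np.asarray(mua, dtype=float))
    musp_arr = np.atleast_1d(np.asarray(musp, dtype=float))
    if mua_arr.shape != musp_arr.shape:
        raise ValueError("mua and musp must have matching shapes")
    if np.any(mua_arr < 0) or np.any(musp_arr <= 0):
        raise ValueError("non-physical target optical properties")
    ratio = musp_arr / base.musp_ref
    if strict and (np.any(ratio < SCALING_RANGE[0])
                   or np.any(ratio > SCALING_RANGE[1])):
        raise ValueError("target mus' outside the validated scaling range "
                         f"{SCALING_RANGE} of the baseline")
    scale = base.musp_ref / musp_arr  # lengths shrink when scattering grows
    g = base.geometry
    out = _scale_records(base.r0, base.d, base.cospsi, base.path, base.weight,
                         base.n_photons, mua_arr, scale,
                         g.collection_offset_cm, g.fiber_radius_cm,
                         g.n_collection)
    if return_se:
        if out.size != 1:
            raise ValueError("SE is available for scalar targets only")
        batch = _scale_records_batched(
            base.r0, base.d, base.cospsi, base.path, base.weight,
            base.photon_idx, base.n_photons, float(mua_arr[0]),
            float(scale[0]), g.collection_offset_cm, g.fiber_radius_cm,
            g.n_collection)
        bsize = base.n_photons // 10
        se = float(np.std(batch / bsize, ddof=1) / np.sqrt(10.0))
        return float(out[0]), se
    if np.isscalar(mua) or np.asarray(mua).ndim == 0:
        return float(out[0])
    return out


def simulate_spectrum(props: OpticalProperties, geom: ProbeGeometry,
                      cfg: MCConfig, base: BaselineSimulation | None = None,
                      strict: bool = True) -> Spectrum:
    """Per-wavelength probe reflectance for full optical property spectra.

    Uses baseline rescaling when a baseline is supplied (fast path; the
    baseline must share the probe geometry), direct MC otherwise.
    """
    if base is not None:
        vals = scale_reflectance(base, props.mua, props.musp, strict=strict)
    else:
        vals = np.array([
            run_direct_mc(float(a), float(s), geom,
                          replace(cfg, rng_seed=cfg.rng_seed + i))
            for i, (a, s) in enumerate(zip(props.mua, props.musp))])
    return Spectrum(grid=props.grid, values=np.clip(vals, 0.0, 1.0),
                    provenance="simulated")


def radial_profile(mua: float, musp: float, geom: ProbeGeometry, cfg: MCConfig,
                   r_edges: np.ndarray) -> np.ndarray:
    """All-angle radial reflectance profile R(rho), cm^-2 per photon.

    Diagnostic estimator used to compare against diffusion theory; unlike the
    probe tally it ignores the collection NA and fiber footprints.
    """
    _check_props(mua, musp)
    mus = musp / (1.0 - cfg.g)
    return _mc_radial(cfg.photon_count, cfg.rng_seed, mus, cfg.g, mua,
                      geom.illum_core_radius_cm, geom.na / geom.n_tissue,
                      geom.n_tissue, geom.n_ext, cfg.max_path_cm,
                      np.asarray(r_edges, dtype=float),
                      cfg.kill_depth_cm, cfg.kill_lateral_cm)
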