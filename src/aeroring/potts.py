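"""Cellular Potts simulator of the spot and microfluidic aerotaxis assays.

Cells are integer-labelled pixel domains (target volume 2 pixels, 1 pixel =
10 um) on a 2-D lattice, evolving by Metropolis-accepted single-pixel copy
attempts (1 Monte Carlo step = one sweep of N*M attempts = 0.1 s). The
Hamiltonian combines a quadratic volume constraint lambda_v (V - V_t)^2 and
an aerotaxis term -lambda_aero(C_cell) * dC across the copy, with the
aerotactic sensitivity and the effective (aerokinetic) temperature both
sigmoidal functions of the oxygen level at the cell's centre of mass:

    lambda_aero(C) = 800 / (1 + exp((C - 0.7)/0.2))
    T(C)           = 85 + 105 / (1 + exp((C - 0.7)/1))

The oxygen field diffuses (2 px^2/step), is consumed at up to 0.1 units per
occupied pixel per step (capped at the available level), leaks in through
the plate bottom at 0.001 * (21 - C)/21 per pixel per step, and is held at
21 % on the borders (spot geometry). Cells divide with probability 1/288000
per step where C >= 0.7 %; division splits a cell into two one-pixel cells
that regrow through the volume constraint, inheriting a lineage tag. In the
microfluidic geometry the oxygen field is frozen to the measured logistic
gradient and neither diffuses nor is consumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from aeroring.params import PottsParams

SPOT_GRID = (500, 500)
MICROFLUIDIC_GRID = (400, 800)       # x by y


@dataclass
class PottsLattice:
    """Lattice state: cell-id grid, per-cell records, coupled oxygen field."""

    grid: np.ndarray                 # int16 (nx, ny), 0 = medium
    O2: np.ndarray                   # float64 (nx, ny), % O2
    volumes: np.ndarray              # int32 (max_cells+1,), index 0 unused
    com_x: np.ndarray                # float64 pixel-coordinate sums
    com_y: np.ndarray
    lineage: np.ndarray              # int32
    n_cells: int
    step: int = 0
    oxygen_mode: str = "dynamic"     # "dynamic" | "frozen"

    def cell_positions(self):
        """Centres of mass (pixels) and lineage of live cells (id order)."""
        ids = np.where(self.volumes[1:self.n_cells + 1] > 0)[0] + 1
        v = self.volumes[ids].astype(float)
        return np.column_stack([self.com_x[ids] / v, self.com_y[ids] / v]), self.lineage[ids]

    def audit_volumes(self) -> bool:
        """Recompute per-cell volumes from the grid and compare."""
        counts = np.bincount(self.grid.ravel(), minlength=self.volumes.size)
        return bool(np.array_equal(counts[1:], self.volumes[1:]))


def _seed_cells(grid, vol, cx, cy, lin, positions, next_id, lineage_of=None):
    nid = next_id
    for k, (x, y) in enumerate(positions):
        if grid[x, y] != 0 or grid[x + 1, y] != 0:
            continue                    # keep seeded cells disjoint
        cid = nid
        grid[x, y] = cid
        grid[x + 1, y] = cid
        vol[cid] = 2
        cx[cid] = 2 * x + 1
        cy[cid] = 2 * y
        lin[cid] = lineage_of[k] if lineage_of is not None else 0
        nid += 1
    return nid


def init_spot(params: PottsParams, scale: float = 1.0) -> PottsLattice:
    """Seed the spot assay: three concentric tiers of decreasing density.

    2-pixel cells on centre grids of pitch (2+g) x (1+g) for gaps g = 1
    (r < 30 px), 2 (30-60 px) and 3 (60-90 px); oxygen 21 % everywhere.
    ``scale`` shrinks the grid and the tier radii together (0.5 for
    desk-scale runs).
    """
    nx = ny = int(round(SPOT_GRID[0] * scale))
    radii = [30.0 * scale, 60.0 * scale, 90.0 * scale]
    gaps = [1, 2, 3]
    cx0, cy0 = nx / 2.0, ny / 2.0
    positions = []
    for tier, (rmax, g) in enumerate(zip(radii, gaps)):
        rmin = 0.0 if tier == 0 else radii[tier - 1]
        px, py = 2 + g, 1 + g
        for x in range(0, nx - 1, px):
            for y in range(0, ny, py):
                rr = math.hypot(x + 1.0 - cx0, y - cy0)  # cell centre
                if rmin <= rr < rmax:
                    positions.append((x, y))
    max_cells = 8 * len(positions) + 64
    grid = np.zeros((nx, ny), dtype=np.int16)
    vol = np.zeros(max_cells + 1, dtype=np.int32)
    comx = np.zeros(max_cells + 1)
    comy = np.zeros(max_cells + 1)
    lin = np.zeros(max_cells + 1, dtype=np.int32)
    n = _seed_cells(grid, vol, comx, comy, lin, positions, 1) - 1
    O2 = np.full((nx, ny), 21.0, dtype=np.float32)
    return PottsLattice(grid, O2, vol, comx, comy, lin, n, oxygen_mode="dynamic")


def init_microfluidic(params: PottsParams, scale: float = 1.0) -> PottsLattice:
    """Seed the microfluidic assay: homogeneous cells in a frozen gradient.

    Two-pixel cells with a six-pixel gap to the next neighbour in all
    directions; the oxygen field is the measured logistic profile
    C(x) = 21.38/(1 + exp(0.031 (x - 200))) (x in pixels), constant in time.
    """
    nx = int(round(MICROFLUIDIC_GRID[0] * scale))
    ny = int(round(MICROFLUIDIC_GRID[1] * scale))
    positions = [
        (x, y) for x in range(0, nx - 1, 8) for y in range(0, ny, 7)
    ]
    max_cells = 8 * len(positions) + 64
    grid = np.zeros((nx, ny), dtype=np.int16)
    vol = np.zeros(max_cells + 1, dtype=np.int32)
    comx = np.zeros(max_cells + 1)
    comy = np.zeros(max_cells + 1)
    lin = np.zeros(max_cells + 1, dtype=np.int32)
    n = _seed_cells(grid, vol, comx, comy, lin, positions, 1) - 1
    x = np.arange(nx, dtype=float) / scale
    from aeroring.synth import microfluidic_oxygen

    O2 = np.repeat(microfluidic_oxygen(x)[:, None], ny, axis=1).astype(np.float32)
    return PottsLattice(grid, O2, vol, comx, comy, lin, n, oxygen_mode="frozen")


@njit(cache=True, fastmath=True)
def _lambda_aero(C, amp, mid, width):
    return amp / (1.0 + math.exp((C - mid) / width))


@njit(cache=True, fastmath=True)
def _temperature(C, base, amp, mid, width):
    return base + amp / (1.0 + math.exp((C - mid) / width))


@njit(cache=True)
def _com_oxygen(O2, cx, cy, vol, cid):
    v = vol[cid]
    i = int(round(cx[cid] / v))
    j = int(round(cy[cid] / v))
    nx, ny = O2.shape
    if i < 0:
        i = 0
    elif i >= nx:
        i = nx - 1
    if j < 0:
        j = 0
    elif j >= ny:
        j = ny - 1
    return O2[i, j]


@njit(cache=True, inline="always")
def _xorshift(s):
    """xorshift64* pseudo-random step; returns (new_state, uint64 draw)."""
    s ^= s >> np.uint64(12)
    s ^= (s << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s ^= s >> np.uint64(27)
    return s, (s * np.uint64(2685821657736338717)) & np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True)
def _mc_sweep(grid, O2, vol, cx, cy,
              lambda_v, V_target, aero_amp, aero_mid, aero_width,
              T_base, T_amp, T_mid, T_width, rng_state, moore):
    """One Monte Carlo step: nx*ny elementary copy attempts.

    A single 64-bit xorshift draw per attempt supplies the target pixel and
    the neighbour direction; a second draw is taken only for the Metropolis
    acceptance of energetically unfavourable copies.
    """
    nx, ny = grid.shape
    n_attempts = nx * ny
    unx = np.uint64(nx)
    uny = np.uint64(ny)
    m32 = np.uint64(0xFFFFFFFF)
    s32 = np.uint64(32)
    s30 = np.uint64(30)
    s62 = np.uint64(62)
    s = rng_state
    for _ in range(n_attempts):
        s, r = _xorshift(s)
        tx = int(np.int64(((r & m32) * unx) >> s32))
        ty = int(np.int64((((r >> s30) & m32) * uny) >> s32))
        if moore:
            d = int(np.int64(r >> np.uint64(61)))
            if d == 8:
                continue
            sxp = tx + (d % 3) - 1
            syp = ty + (d // 3) - 1
            if sxp == tx and syp == ty:       # d == 4 is the null offset
                sxp, syp = tx + 1, ty + 1
        else:
            d = int(np.int64(r >> s62))
            if d == 0:
                sxp, syp = tx - 1, ty
            elif d == 1:
                sxp, syp = tx + 1, ty
            elif d == 2:
                sxp, syp = tx, ty - 1
            else:
                sxp, syp = tx, ty + 1
        if sxp < 0 or sxp >= nx or syp < 0 or syp >= ny:
            continue
        sid = grid[sxp, syp]
        tid = grid[tx, ty]
        if sid == tid:
            continue
        if tid > 0 and vol[tid] <= 1:
            continue                    # no cell death
        dH = 0.0
        if sid > 0:
            v = vol[sid]
            dH += lambda_v * ((v + 1.0 - V_target) ** 2 - (v - V_target) ** 2)
        if tid > 0:
            v = vol[tid]
            dH += lambda_v * ((v - 1.0 - V_target) ** 2 - (v - V_target) ** 2)
        # aerotaxis as the potential H = -lambda_aero(C_cell) * sum_px C(px):
        # a cell gains -lambda*C_t by occupying the target pixel and pays
        # +lambda*C_t for losing it, so both expansion and retraction bias
        # the cell up-gradient (for a fixed source pixel the -lambda*C_s
        # offset of the copy form is direction-neutral). The copy is judged
        # at the moving cell's temperature: aerokinesis is a cell property.
        Ct = O2[tx, ty]
        if sid > 0:
            Ccell = _com_oxygen(O2, cx, cy, vol, sid)
            dH -= _lambda_aero(Ccell, aero_amp, aero_mid, aero_width) * (Ct - O2[sxp, syp])
            T = _temperature(Ccell, T_base, T_amp, T_mid, T_width)
            if tid > 0:
                Ccell2 = _com_oxygen(O2, cx, cy, vol, tid)
                dH += _lambda_aero(Ccell2, aero_amp, aero_mid, aero_width) * Ct
        else:
            Ccell = _com_oxygen(O2, cx, cy, vol, tid)
            dH += _lambda_aero(Ccell, aero_amp, aero_mid, aero_width) * Ct
            T = _temperature(Ccell, T_base, T_amp, T_mid, T_width)
        if dH > 0.0:
            s, r2 = _xorshift(s)
            u = (r2 >> np.uint64(11)) * (1.0 / 9007199254740992.0)
            if u >= math.exp(-dH / T):
                continue
        # accept: copy source id onto target pixel
        grid[tx, ty] = sid
        if sid > 0:
            vol[sid] += 1
            cx[sid] += tx
            cy[sid] += ty
        if tid > 0:
            vol[tid] -= 1
            cx[tid] -= tx
            cy[tid] -= ty
    return s


@njit(cache=True, fastmath=True)
def _oxygen_update(grid, O2, Dox_px, consumption, leak, scratch):
    """Explicit diffusion (stable substeps) + capped consumption + leak.

    Dirichlet C = 21 on the borders: the domain edges act as an oxygen
    source, like the coverslip edges in the experiment.
    """
    nx, ny = O2.shape
    nsub = int(math.ceil(Dox_px / 0.24))
    dsub = Dox_px / nsub
    for _ in range(nsub):
        for i in range(1, nx - 1):
            for j in range(1, ny - 1):
                scratch[i, j] = O2[i, j] + dsub * (
                    O2[i - 1, j] + O2[i + 1, j] + O2[i, j - 1] + O2[i, j + 1]
                    - 4.0 * O2[i, j]
                )
        for i in range(1, nx - 1):
            for j in range(1, ny - 1):
                O2[i, j] = scratch[i, j]
    for i in range(1, nx - 1):
        for j in range(1, ny - 1):
            c = O2[i, j]
            if grid[i, j] > 0:
                use = consumption if c > consumption else c
                c -= use
            c += leak * (21.0 - c) / 21.0
            O2[i, j] = c
    for i in range(nx):
        O2[i, 0] = 21.0
        O2[i, ny - 1] = 21.0
    for j in range(ny):
        O2[0, j] = 21.0
        O2[nx - 1, j] = 21.0


@njit(cache=True)
def _divide_cells(grid, O2, vol, cx, cy, lin, n_cells, prob, cutoff):
    """Random divisions: each cell with local C >= cutoff divides w.p. prob.

    A dividing cell donates one of its pixels to a new one-pixel cell that
    regrows through the volume constraint; the lineage tag is inherited.
    """
    n = n_cells
    if prob <= 0.0 or n == 0:
        return n
    n_cand = np.random.binomial(n, prob)
    for _ in range(n_cand):
        cid = 1 + np.random.randint(n)
        v = vol[cid]
        if v < 2:
            continue
        if _com_oxygen(O2, cx, cy, vol, cid) < cutoff:
            continue
        # locate one pixel of the cell near its centre of mass
        ci = int(round(cx[cid] / v))
        cj = int(round(cy[cid] / v))
        nx, ny = grid.shape
        found_i, found_j = -1, -1
        for r in range(0, 4):
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    i = ci + di
                    j = cj + dj
                    if 0 <= i < nx and 0 <= j < ny and grid[i, j] == cid:
                        found_i, found_j = i, j
                        break
                if found_i >= 0:
                    break
            if found_i >= 0:
                break
        if found_i < 0:
            continue
        if n + 1 >= vol.size - 1:
            continue                    # capacity guard
        n += 1
        new_id = n
        grid[found_i, found_j] = new_id
        vol[cid] -= 1
        cx[cid] -= found_i
        cy[cid] -= found_j
        vol[new_id] = 1
        cx[new_id] = found_i
        cy[new_id] = found_j
        lin[new_id] = lin[cid]
    return n


@njit(cache=True)
def _run_kernel(grid, O2, vol, cx, cy, lin, n_cells,
                n_mcs, record_stride, dynamic_oxygen,
                lambda_v, V_target, aero_amp, aero_mid, aero_width,
                T_base, T_amp, T_mid, T_width,
                Dox_px, consumption, leak, div_prob, div_cutoff,
                seed, moore,
                rec_pos, rec_lin, rec_nc, rec_O2):
    np.random.seed(seed)
    rng_state = (np.uint64(seed) * np.uint64(6364136223846793005)
                 + np.uint64(1442695040888963407))
    if rng_state == np.uint64(0):
        rng_state = np.uint64(0x9E3779B97F4A7C15)
    scratch = np.zeros_like(O2)
    rec = 0
    for s in range(1, n_mcs + 1):
        rng_state = _mc_sweep(grid, O2, vol, cx, cy,
                              lambda_v, V_target, aero_amp, aero_mid, aero_width,
                              T_base, T_amp, T_mid, T_width, rng_state, moore)
        if dynamic_oxygen:
            _oxygen_update(grid, O2, Dox_px, consumption, leak, scratch)
        n_cells = _divide_cells(grid, O2, vol, cx, cy, lin, n_cells,
                                div_prob, div_cutoff)
        if s % record_stride == 0 and rec < rec_nc.size:
            rec_nc[rec] = n_cells
            for cid in range(1, n_cells + 1):
                v = vol[cid]
                if v > 0:
                    rec_pos[rec, cid - 1, 0] = cx[cid] / v
                    rec_pos[rec, cid - 1, 1] = cy[cid] / v
                else:
                    rec_pos[rec, cid - 1, 0] = np.nan
                    rec_pos[rec, cid - 1, 1] = np.nan
                rec_lin[rec, cid - 1] = lin[cid]
            for i in range(O2.shape[0]):
                for j in range(O2.shape[1]):
                    rec_O2[rec, i, j] = O2[i, j]
            rec += 1
    return n_cells


def _rng_state(seed: int) -> np.uint64:
    s = (int(seed) * 6364136223846793005 + 1442695040888963407) & 0xFFFFFFFFFFFFFFFF
    return np.uint64(s) if s else np.uint64(0x9E3779B97F4A7C15)


def mc_step(lattice: PottsLattice, params: PottsParams, seed: int = 0,
            n_steps: int = 1) -> PottsLattice:
    """Advance the lattice by ``n_steps`` Monte Carlo steps (in place)."""
    s = _rng_state(seed)
    moore = params.neighborhood == "moore"
    for _ in range(n_steps):
        s = _mc_sweep(lattice.grid, lattice.O2, lattice.volumes,
                      lattice.com_x, lattice.com_y,
                      params.lambda_v, float(params.V_target),
                      params.lambda_aero_max, params.aero_midpoint,
                      params.aero_width, params.T_base, params.T_amp,
                      params.T_midpoint, params.T_width, s, moore)
    lattice.step += n_steps
    return lattice


def update_oxygen(lattice: PottsLattice, params: PottsParams) -> PottsLattice:
    """One oxygen step: diffusion, capped consumption, leak, 21 % borders."""
    if lattice.oxygen_mode != "dynamic":
        raise ValueError("oxygen update requires dynamic oxygen mode")
    _oxygen_update(lattice.grid, lattice.O2, params.Dox_px,
                   params.consumption_per_pixel, params.leak_coeff,
                   np.zeros_like(lattice.O2))
    return lattice


@njit(cache=True)
def _seed_numba_rng(seed):
    np.random.seed(seed)


def maybe_divide(lattice: PottsLattice, params: PottsParams,
                 seed: int | None = None) -> PottsLattice:
    """One round of random divisions gated at C >= division_cutoff."""
    if seed is not None:
        _seed_numba_rng(seed)       # numba keeps its own RNG state
    lattice.n_cells = int(_divide_cells(
        lattice.grid, lattice.O2, lattice.volumes, lattice.com_x,
        lattice.com_y, lattice.lineage, lattice.n_cells,
        params.division_prob, params.division_cutoff,
    ))
    return lattice


VARIANTS = ("full", "no_division", "constant_T", "wide_aero", "flat_aero",
            "low_consumption")


def apply_variant(params: PottsParams, variant: str,
                  constant_T: float = 135.0) -> PottsParams:
    """Return a parameter set remapped for one of the ablation variants."""
    import dataclasses

    if variant == "full":
        return params
    if variant == "no_division":
        return dataclasses.replace(params, division_prob=0.0)
    if variant == "constant_T":
        # aerokinesis off: temperature independent of oxygen
        return dataclasses.replace(params, T_base=constant_T, T_amp=1e-12)
    if variant == "wide_aero":
        return dataclasses.replace(params, lambda_aero_max=1225.0, aero_width=1.5)
    if variant == "flat_aero":
        # no modulation: full aerotactic strength at all oxygen levels
        return dataclasses.replace(params, aero_width=1e6, lambda_aero_max=2 * 800.0)
    if variant == "low_consumption":
        return dataclasses.replace(
            params, consumption_per_pixel=params.consumption_per_pixel / 3.0
        )
    raise ValueError(f"unknown variant {variant!r}")


@dataclass
class PottsRun:
    """Recorded time series of a Potts assay simulation."""

    times_min: np.ndarray            # minutes
    positions_um: list               # per snapshot: (n_cells, 2) um
    lineages: list                   # per snapshot: (n_cells,) int
    n_cells: np.ndarray
    O2_snapshots: np.ndarray         # (n_rec, nx, ny) float32, % O2
    params: PottsParams
    geometry: str
    variant: str
    scale: float
    lattice: PottsLattice            # final state


def save_run(run: "PottsRun", directory) -> None:
    """Write a run's oxygen stack (multi-page TIFF) and per-cell tables.

    ``<dir>/oxygen.tif`` holds one float32 page per snapshot; each
    ``<dir>/cells_tXXXX.csv`` lists id, x_um, y_um, lineage for one
    snapshot.
    """
    import tifffile
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(d / "oxygen.tif", run.O2_snapshots)
    for t, pos, lin in zip(run.times_min, run.positions_um, run.lineages):
        ids = np.arange(1, len(pos) + 1)
        table = np.column_stack([ids, pos[:, 0], pos[:, 1], lin])
        np.savetxt(
            d / f"cells_t{int(round(t)):05d}.csv", table,
            fmt=["%d", "%.2f", "%.2f", "%d"], delimiter=",",
            header="id,x_um,y_um,lineage", comments="",
        )


def run_assay(
    geometry: str,
    params: PottsParams | None = None,
    t_end_h: float = 4.0,
    variant: str = "full",
    seed: int = 1,
    scale: float = 1.0,
    record_every_min: float = 10.0,
    tag_radial_halves: bool = False,
) -> PottsRun:
    """Run a spot or microfluidic assay and record cell positions and oxygen.

    Deterministic for a fixed seed. ``scale`` = 0.5 runs the desk-scale
    250x250 spot (radii halved); times are converted with 1 MCS = 0.1 s.
    ``tag_radial_halves`` assigns lineage tag 1/2 to the inner/outer radial
    half of the seeded colony (inert two-colour labeling, inherited on
    division) for pushed-wave mixing analyses.
    """
    params = params or PottsParams()
    params = apply_variant(params, variant)
    if geometry == "spot":
        lat = init_spot(params, scale=scale)
    elif geometry == "microfluidic":
        lat = init_microfluidic(params, scale=scale)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    if tag_radial_halves:
        pos, _ = lat.cell_positions()
        c0 = np.array(lat.grid.shape, dtype=float) / 2.0
        r = np.linalg.norm(pos - c0, axis=1)
        med = np.median(r)
        lat.lineage[1:lat.n_cells + 1] = np.where(r <= med, 1, 2)
    steps_per_min = 60.0 / params.step_s
    n_mcs = int(round(t_end_h * 60.0 * steps_per_min))
    stride = max(1, int(round(record_every_min * steps_per_min)))
    n_rec = n_mcs // stride
    max_cells = lat.volumes.size - 1
    rec_pos = np.full((n_rec, max_cells, 2), np.nan, dtype=np.float32)
    rec_lin = np.zeros((n_rec, max_cells), dtype=np.int32)
    rec_nc = np.zeros(n_rec, dtype=np.int64)
    rec_O2 = np.zeros((n_rec, *lat.O2.shape), dtype=np.float32)
    dynamic = lat.oxygen_mode == "dynamic"
    n_cells = _run_kernel(
        lat.grid, lat.O2, lat.volumes, lat.com_x, lat.com_y, lat.lineage,
        lat.n_cells, n_mcs, stride, dynamic,
        params.lambda_v, float(params.V_target),
        params.lambda_aero_max, params.aero_midpoint, params.aero_width,
        params.T_base, params.T_amp, params.T_midpoint, params.T_width,
        params.Dox_px, params.consumption_per_pixel, params.leak_coeff,
        params.division_prob if dynamic or geometry == "spot" else 0.0,
        params.division_cutoff, seed, params.neighborhood == "moore",
        rec_pos, rec_lin, rec_nc, rec_O2,
    )
    lat.n_cells = int(n_cells)
    lat.step = n_mcs
    times = (np.arange(1, n_rec + 1) * stride) / steps_per_min
    px_um = params.px_um
    positions, lineages = [], []
    for k in range(n_rec):
        nc = int(rec_nc[k])
        pos = rec_pos[k, :nc].astype(float) * px_um
        ok = np.isfinite(pos[:, 0])
        positions.append(pos[ok])
        lineages.append(rec_lin[k, :nc][ok])
    return PottsRun(times, positions, lineages, rec_nc.copy(), rec_O2,
                    params, geometry, variant, scale, lat)
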