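"""Synthetic longitudinal and snapshot nucleus clouds.

This module emulates the statistical structure of the imaging data the
analysis stages assume, so every downstream stage can be exercised and
verified without any external download:

* a hard-core spatial point process for nucleus centroids (nuclei cannot
  overlap, which gives cortical fields their regular spacing);
* weekly death with tangle-status-dependent hazards, coupled to the local
  microstructure so that neurons in sparse neighbourhoods die more often;
* a radial displacement ramp of each doomed neuron's four designated
  persistent neighbours over the final pre-death window, calibrated so the
  neighbour tetrahedron volume grows by a configurable percentage;
* per-session similarity-transform misalignment with octant-distributed
  fiducial landmarks, plus centroid measurement jitter;
* a human-like single-snapshot cloud containing a small subpopulation of
  neurons in locally rarefied neighbourhoods ("enlarged" microstructure);
* a simple Gaussian-blob renderer and detector for voxel-level fixtures.

Fixed seeds give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from .cloud import SessionCloud
from .imaging import DEFAULT_VOXEL_SIZE_UM
from .registration import SimilarityTransform
from .tracking import DEFAULT_EDGE_MARGIN_UM

__all__ = [
    "PackingError",
    "SimulationConfig",
    "SnapshotConfig",
    "GroundTruth",
    "generate_base_cloud",
    "simulate_longitudinal",
    "generate_snapshot",
    "render_stack",
    "detect_blobs",
    "fate_agreement",
]


class PackingError(RuntimeError):
    """Dart throwing could not place the requested points at the given density."""


#: Largest week-to-week displacement a ramped neighbour may take.  The
#: week-to-week match distance is the jump plus centroid jitter, so this
#: stays far enough below the default 8 um tracking gate that the planted
#: rearrangement never severs the neighbour's own track.
_MAX_WEEKLY_JUMP_UM = 5.0


# --------------------------------------------------------------------------
# configs
# --------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Parameters of the longitudinal simulation.

    Defaults emulate one imaged field of the aggressive tauopathy regime:
    a 509 x 509 x 200 um volume holding ~1,500 labelled nuclei at a 12 um
    hard-core separation, imaged weekly for 4 weeks.  Non-tangle-bearing
    neurons die at ~3.6%/week, tangle-bearing at ~1%/week, and a dying
    neuron's designated neighbours drift radially outward over its final
    2-week window so that their tetrahedron volume grows by 29.5%.
    ``sparsity_coupling`` biases death toward neurons with large baseline
    3-NN distances (hazard weight proportional to ``d3**coupling``,
    normalised to preserve the mean hazard), reproducing the observation
    that doomed neurons already sit in rarefied neighbourhoods.
    """

    bounds: tuple = ((0.0, 0.0, 0.0), (509.0, 509.0, 200.0))
    n_neurons: int = 1500
    min_separation: float = 12.0
    n_weeks: int = 4
    p_tangle_init: float = 0.074
    tangle_rate: float = 0.022
    hazard_nontangle: float = 0.036
    hazard_tangle: float = 0.010
    ramp_weeks: int = 2
    ramp_volume_pct: float = 29.5
    jitter_sd: float = 0.5
    session_transforms: list | None = None
    n_fiducials: int = 8
    sparsity_coupling: float = 2.0
    hazard_change_week: int | None = None
    hazard_change_factor: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        problems = []
        lo, hi = np.asarray(self.bounds[0], float), np.asarray(self.bounds[1], float)
        if np.any(hi - lo <= 0):
            problems.append("bounds must span a positive volume")
        if self.min_separation <= 0:
            problems.append("min_separation must be > 0")
        for name in ("hazard_nontangle", "hazard_tangle", "p_tangle_init", "tangle_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name} must lie in [0, 1]")
        if self.n_weeks < 1:
            problems.append("n_weeks must be >= 1")
        if not 1 <= self.ramp_weeks < self.n_weeks:
            problems.append("ramp_weeks must satisfy 1 <= ramp_weeks < n_weeks")
        if self.jitter_sd < 0:
            problems.append("jitter_sd must be >= 0")
        if self.session_transforms is not None and len(self.session_transforms) != self.n_weeks:
            problems.append("session_transforms must supply one transform per week")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))

    def bounds_array(self) -> np.ndarray:
        return np.asarray(self.bounds, dtype=float).reshape(2, 3)


@dataclass
class SnapshotConfig:
    """Parameters of the single-time-point, human-like snapshot cloud.

    Defaults place 20,000 nuclei in a 1 x 1 x 0.5 mm cleared-tissue block
    (mean 3-NN distance ~21 um).  A 2% subpopulation sits in locally
    rarefied neighbourhoods whose 3-NN distance exceeds the local average
    by ``enlargement_pct`` percent, and only 9.3% of those carry a tangle.
    """

    bounds: tuple = ((0.0, 0.0, 0.0), (1000.0, 1000.0, 500.0))
    n_neurons: int = 20000
    min_separation: float = 12.0
    enlarged_fraction: float = 0.02
    enlargement_pct: float = 80.0
    tangle_fraction: float = 0.10
    tangle_on_enlarged_fraction: float = 0.093
    seed: int = 0

    def validate(self) -> None:
        problems = []
        lo, hi = np.asarray(self.bounds[0], float), np.asarray(self.bounds[1], float)
        if np.any(hi - lo <= 0):
            problems.append("bounds must span a positive volume")
        if self.min_separation <= 0:
            problems.append("min_separation must be > 0")
        for name in ("enlarged_fraction", "tangle_fraction", "tangle_on_enlarged_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                problems.append(f"{name} must lie in [0, 1]")
        if self.enlargement_pct <= 0:
            problems.append("enlargement_pct must be > 0")
        if problems:
            raise ValueError("invalid SnapshotConfig: " + "; ".join(problems))

    def bounds_array(self) -> np.ndarray:
        return np.asarray(self.bounds, dtype=float).reshape(2, 3)


@dataclass
class GroundTruth:
    """Per-neuron truth of a longitudinal simulation.

    ``fates`` maps neuron id to ``{"fate": "persisted"}`` or
    ``{"fate": "disappeared", "death_week": w}`` with ``w`` the first week
    the neuron is absent.  ``ramp_neighbors`` lists, for each dying neuron
    that received a displacement ramp, the ids of its four displaced
    persistent neighbours.
    """

    fates: dict
    tangle_onset: dict
    transforms: list
    ramp_neighbors: dict
    config: SimulationConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fates": {str(k): v for k, v in self.fates.items()},
            "tangle_onset": {str(k): v for k, v in self.tangle_onset.items()},
            "transforms": [t.to_dict() for t in self.transforms],
            "ramp_neighbors": {str(k): [int(i) for i in v] for k, v in self.ramp_neighbors.items()},
            "config": _config_to_jsonable(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        cfg_d = d["config"]
        cfg_d["bounds"] = tuple(tuple(b) for b in cfg_d["bounds"])
        cfg = SimulationConfig(**cfg_d)
        return cls(
            fates={int(k): v for k, v in d["fates"].items()},
            tangle_onset={int(k): v for k, v in d["tangle_onset"].items()},
            transforms=[SimilarityTransform.from_dict(t) for t in d["transforms"]],
            ramp_neighbors={int(k): v for k, v in d["ramp_neighbors"].items()},
            config=cfg,
        )


def _config_to_jsonable(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["session_transforms"] = None  # stored separately under "transforms"
    return d


# --------------------------------------------------------------------------
# hard-core point process
# --------------------------------------------------------------------------

_NEIGHBOR_OFFSETS = [
    (i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
]


def _hard_core_points(
    n: int,
    bounds: np.ndarray,
    min_sep: float,
    rng: np.random.Generator,
    max_attempts_per_point: int = 500,
) -> np.ndarray:
    """Dart throwing with a cell-list acceptance test.

    Proposes uniform points and rejects any closer than ``min_sep`` to an
    accepted point; raises :class:`PackingError` when the attempt budget is
    exhausted (density infeasible for the requested separation).
    """
    lo, hi = bounds
    span = hi - lo
    cell = float(min_sep)
    grid: dict[tuple[int, int, int], list[int]] = {}
    pts = np.empty((n, 3))
    min_sep2 = min_sep * min_sep
    count = 0
    budget = max_attempts_per_point * max(n, 1)
    attempts = 0
    while count < n:
        if attempts >= budget:
            raise PackingError(
                f"placed only {count}/{n} points at min_separation={min_sep} "
                f"within {budget} attempts; density appears infeasible"
            )
        p = lo + rng.random(3) * span
        attempts += 1
        ci = int((p[0] - lo[0]) // cell)
        cj = int((p[1] - lo[1]) // cell)
        ck = int((p[2] - lo[2]) // cell)
        ok = True
        for di, dj, dk in _NEIGHBOR_OFFSETS:
            bucket = grid.get((ci + di, cj + dj, ck + dk))
            if not bucket:
                continue
            q = pts[bucket]
            if np.min(np.sum((q - p) ** 2, axis=1)) < min_sep2:
                ok = False
                break
        if ok:
            pts[count] = p
            grid.setdefault((ci, cj, ck), []).append(count)
            count += 1
    return pts


def _mean_knn_distance(xyz: np.ndarray, k: int = 3) -> np.ndarray:
    tree = cKDTree(xyz)
    d, _ = tree.query(xyz, k=k + 1)
    return d[:, 1:].mean(axis=1)


def _select_fiducials(
    xyz: np.ndarray, bounds: np.ndarray, n_fid: int, rng: np.random.Generator
) -> np.ndarray:
    """Pick one landmark per box octant (4 upper / 4 lower for the default 8)."""
    lo, hi = bounds
    mid = (lo + hi) / 2.0
    octant = (
        (xyz[:, 0] > mid[0]).astype(int)
        + 2 * (xyz[:, 1] > mid[1]).astype(int)
        + 4 * (xyz[:, 2] > mid[2]).astype(int)
    )
    chosen: list[int] = []
    taken = np.zeros(len(xyz), dtype=bool)
    n_fid = min(n_fid, len(xyz))  # tiny clouds: every neuron is a landmark
    o = 0
    while len(chosen) < n_fid:
        cand = np.flatnonzero((octant == o % 8) & ~taken)
        if len(cand) == 0:
            cand = np.flatnonzero(~taken)
        pick = int(rng.choice(cand))
        chosen.append(pick)
        taken[pick] = True
        o += 1
    return np.sort(np.array(chosen, dtype=int))


# --------------------------------------------------------------------------
# longitudinal simulation
# --------------------------------------------------------------------------


def _base_cloud(config: SimulationConfig, rng: np.random.Generator) -> SessionCloud:
    bounds = config.bounds_array()
    xyz = _hard_core_points(config.n_neurons, bounds, config.min_separation, rng)
    tangle = rng.random(config.n_neurons) < config.p_tangle_init
    fiducial = np.zeros(config.n_neurons, dtype=bool)
    fiducial[_select_fiducials(xyz, bounds, config.n_fiducials, rng)] = True
    return SessionCloud(
        xyz=xyz,
        ids=np.arange(config.n_neurons, dtype=np.int64),
        tangle=tangle,
        fiducial=fiducial,
        bounds=bounds,
        week=1,
    )


def _tetra_vol(verts: np.ndarray) -> float:
    return abs(np.linalg.det(verts[1:] - verts[0])) / 6.0


def _expected_crop_box(
    bounds: np.ndarray, transforms: list[SimilarityTransform]
) -> tuple[np.ndarray, np.ndarray]:
    """Common overlap box in the reference (week-1 session) frame."""
    lo, hi = bounds
    corners = np.array(
        [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
    )
    ref = transforms[0]
    los, his = [], []
    for t_w in transforms:
        sess = t_w.apply(corners)
        aabb = np.array(
            [
                [x, y, z]
                for x in (sess[:, 0].min(), sess[:, 0].max())
                for y in (sess[:, 1].min(), sess[:, 1].max())
                for z in (sess[:, 2].min(), sess[:, 2].max())
            ]
        )
        back = ref.compose(t_w.inverse()).apply(aabb)
        los.append(back.min(axis=0))
        his.append(back.max(axis=0))
    return np.max(los, axis=0), np.min(his, axis=0)


def _solve_ramp_displacements(
    config: SimulationConfig,
    base: SessionCloud,
    death_week: np.ndarray,
    jitter: dict,
    transforms: list[SimilarityTransform],
) -> tuple[dict, dict]:
    """Radial pre-death displacement fields hitting the target volume ratio.

    Each dying neuron observed for at least ``ramp_weeks`` weeks pushes
    its 4 nearest persistent neighbours radially outward over its final
    observed window.  The neighbour set is chosen exactly as the analysis
    stage will see it: distances are taken between jittered positions in
    the reference frame, and candidates must remain inside the expected
    all-week crop box so that their tracks survive registration and
    cropping.  Neighbours shared between nearby dying neurons make the
    per-neuron volume ratios coupled, so the per-neuron push magnitudes
    are solved jointly by Gauss-Seidel sweeps: each rescales one neuron's
    push so that, given everyone else's current field, its
    neighbour-tetrahedron volume over the pre-death window grows by
    exactly ``ramp_volume_pct`` percent.

    Returns ``(disp, ramp_neighbors)`` where ``disp[t]`` is the (n, 3)
    displacement field of week ``t``.
    """
    n = base.n
    lam = (1.0 + config.ramp_volume_pct / 100.0) ** (1.0 / 3.0)
    target = (1.0 + config.ramp_volume_pct / 100.0)
    weeks = range(1, config.n_weeks + 1)

    # crop-safe candidates: observed position inside the overlap box (with
    # the tracking guard band) every week, so the candidate's track will
    # survive registration, cropping and edge censoring
    crop_lo, crop_hi = _expected_crop_box(base.bounds, transforms)
    ref = transforms[0]
    safe = np.ones(n, dtype=bool)
    obs_ref_by_week = {}
    for t in weeks:
        obs_ref = ref.compose(transforms[t - 1].inverse()).apply(
            transforms[t - 1].apply(base.xyz) + jitter[t]
        )
        obs_ref_by_week[t] = obs_ref
        safe &= np.all(
            (obs_ref >= crop_lo + DEFAULT_EDGE_MARGIN_UM)
            & (obs_ref <= crop_hi - DEFAULT_EDGE_MARGIN_UM),
            axis=1,
        )

    persistent = (death_week == 0) & ~base.fiducial & safe
    cand = np.flatnonzero(persistent)
    disp = {t: np.zeros((n, 3)) for t in weeks}
    ramp_neighbors: dict[int, list[int]] = {}
    if len(cand) < 4:
        return disp, ramp_neighbors

    # selection distances as the analysis sees them: jittered week-1
    # positions in the reference frame (ordering is similarity-invariant)
    sel_xyz = ref.apply(base.xyz) + jitter[1]

    # ramp profile: zero through the window start, full push at the last
    # observed week, held constant afterwards
    defs = []  # (focal, nbrs(4,), profile: week -> fraction of full push)
    dying = sorted(np.flatnonzero(death_week > 0), key=lambda i: (death_week[i], i))
    for i in dying:
        wk = int(death_week[i])
        start = wk - config.ramp_weeks
        if start < 1:
            continue  # pre-death window not fully observed
        dist = np.linalg.norm(sel_xyz[cand] - sel_xyz[i], axis=1)
        order = np.lexsort((cand, dist))
        nbrs = cand[order[:4]]
        ramp_neighbors[int(i)] = [int(j) for j in nbrs]
        denom = max(config.ramp_weeks - 1, 1)
        profile = {
            t: min(1.0, (t - start) / denom) for t in weeks if t > start
        }
        defs.append((int(i), nbrs, profile))

    if not defs:
        return disp, ramp_neighbors

    by_vertex: dict[int, list[int]] = {}
    for di, (_, nbrs, _) in enumerate(defs):
        for j in nbrs:
            by_vertex.setdefault(int(j), []).append(di)

    n_defs = len(defs)
    amps = np.full(n_defs, lam - 1.0)
    # per-vertex multipliers: a vertex whose accumulated week-step jump
    # would exceed the cap gets its share scaled down, and the solver
    # compensates through the neuron's unconstrained vertices
    vert_scale = np.ones((n_defs, 4))
    dists = np.empty((n_defs, 4))
    for di, (focal, nbrs, _) in enumerate(defs):
        dists[di] = np.linalg.norm(base.xyz[nbrs] - base.xyz[focal], axis=1)
    vert_idx = {
        (di, int(j)): k for di, (_, nbrs, _) in enumerate(defs) for k, j in enumerate(nbrs)
    }

    def vertex_pos(j: int, t: int) -> np.ndarray:
        p = base.xyz[j].copy()
        for di in by_vertex.get(int(j), ()):
            focal, _, profile = defs[di]
            frac = profile.get(t, 0.0)
            if frac:
                k = vert_idx[(di, int(j))]
                p += amps[di] * vert_scale[di, k] * frac * (base.xyz[j] - base.xyz[focal])
        return p

    def window_ratio(di: int) -> float:
        focal, nbrs, _ = defs[di]
        wk = int(death_week[focal])
        v0 = _tetra_vol(np.stack([vertex_pos(j, wk - 2) for j in nbrs]))
        v1 = _tetra_vol(np.stack([vertex_pos(j, wk - 1) for j in nbrs]))
        return v1 / v0 if v0 > 0 else np.inf

    all_uncoupled = all(
        len(by_vertex[int(j)]) == 1 for _, nbrs, _ in defs for j in nbrs
    )
    max_steps = np.empty(n_defs)
    for di, (_, _, profile) in enumerate(defs):
        fr = [0.0] + [profile.get(t, 0.0) for t in weeks]
        max_steps[di] = max(abs(b - a) for a, b in zip(fr[:-1], fr[1:]))

    def def_cap(di: int) -> float:
        # no individual vertex may jump more than the weekly cap in one step
        per_vertex = _MAX_WEEKLY_JUMP_UM / (
            max_steps[di] * dists[di] * np.maximum(vert_scale[di], 1e-9)
        )
        return float(min(4.0 * (lam - 1.0), per_vertex.min()))

    amps = np.minimum(amps, [def_cap(di) for di in range(n_defs)])

    def solve_one(di: int) -> float:
        def err(a: float) -> float:
            amps[di] = a
            return window_ratio(di) - target

        if abs(err(amps[di])) < 1e-9:
            return amps[di]
        grid = np.linspace(0.0, def_cap(di), 17)
        vals = np.array([err(a) for a in grid])
        sign_change = np.flatnonzero(np.diff(np.sign(vals)) != 0)
        if len(sign_change):
            k = sign_change[0]
            lo_a, hi_a = grid[k], grid[k + 1]
            flo = vals[k]
            for _ in range(40):  # bisection on the bracket
                mid = 0.5 * (lo_a + hi_a)
                fm = err(mid)
                if abs(fm) < 1e-10:
                    return mid
                if (fm > 0) == (flo > 0):
                    lo_a, flo = mid, fm
                else:
                    hi_a = mid
            return 0.5 * (lo_a + hi_a)
        # no root in range: bounded best effort
        return float(grid[int(np.argmin(np.abs(vals)))])

    n_sweeps = 1 if all_uncoupled else 8
    for _ in range(n_sweeps):
        for di in range(n_defs):
            amps[di] = solve_one(di)

    # Two further per-vertex feasibility constraints, enforced by scaling
    # down the offending vertex's multiplier and re-solving so the other
    # vertices compensate: (1) vertices shared between dying neurons
    # accumulate several pushes, whose TOTAL week-step jump must also stay
    # under the cap; (2) a displaced vertex must not drift into the edge
    # guard band, or its own track would be censored.
    week_list = list(weeks)
    ref_lin = ref.scale * ref.rotation
    margin = DEFAULT_EDGE_MARGIN_UM + 0.5  # slack for transform estimation
    for _ in range(5):
        violated = False

        def total_disp(j: int, t: int) -> np.ndarray:
            d = np.zeros(3)
            for di in by_vertex[j]:
                focal, _, profile = defs[di]
                frac = profile.get(t, 0.0)
                if frac:
                    k = vert_idx[(di, j)]
                    d += amps[di] * vert_scale[di, k] * frac * (
                        base.xyz[j] - base.xyz[focal]
                    )
            return d

        for j, dis in by_vertex.items():
            if len(dis) > 1:  # single-def vertices already jump-capped
                for t0, t1 in zip(week_list[:-1], week_list[1:]):
                    delta = total_disp(j, t1) - total_disp(j, t0)
                    nrm = float(np.linalg.norm(delta))
                    if nrm > _MAX_WEEKLY_JUMP_UM * 1.001:
                        violated = True
                        s = _MAX_WEEKLY_JUMP_UM / nrm
                        for di in dis:
                            vert_scale[di, vert_idx[(di, j)]] *= s
            for t in week_list:
                d = total_disp(j, t)
                if not d.any():
                    continue
                obs = obs_ref_by_week[t][j] + ref_lin @ d
                over_hi = obs - (crop_hi - margin)
                over_lo = (crop_lo + margin) - obs
                if np.all(over_hi <= 0) and np.all(over_lo <= 0):
                    continue
                violated = True
                d_ref = ref_lin @ d
                alpha = 1.0
                obs0 = obs_ref_by_week[t][j]
                for ax in range(3):
                    if over_hi[ax] > 0 and d_ref[ax] > 0:
                        alpha = min(alpha, (crop_hi[ax] - margin - obs0[ax]) / d_ref[ax])
                    if over_lo[ax] > 0 and d_ref[ax] < 0:
                        alpha = min(alpha, (crop_lo[ax] + margin - obs0[ax]) / d_ref[ax])
                alpha = max(alpha, 0.0)
                for di in by_vertex[j]:
                    vert_scale[di, vert_idx[(di, j)]] *= alpha
        if not violated:
            break
        for _ in range(3):
            for di in range(n_defs):
                amps[di] = solve_one(di)

    for di, (focal, nbrs, profile) in enumerate(defs):
        push = (amps[di] * vert_scale[di])[:, None] * (base.xyz[nbrs] - base.xyz[focal])
        for t, frac in profile.items():
            disp[t][nbrs] += frac * push
    return disp, ramp_neighbors


def generate_base_cloud(config: SimulationConfig) -> SessionCloud:
    """Week-1 truth cloud: hard-core centroids with tangle and fiducial flags."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    return _base_cloud(config, rng)


def _default_transforms(
    n_weeks: int, rng: np.random.Generator
) -> list[SimilarityTransform]:
    """Mild per-session misalignments; week 1 is the identity reference."""
    out = [SimilarityTransform.identity()]
    for _ in range(n_weeks - 1):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(rng.uniform(0.5, 3.0))
        k = np.array(
            [
                [0, -axis[2], axis[1]],
                [axis[2], 0, -axis[0]],
                [-axis[1], axis[0], 0],
            ]
        )
        rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
        scale = rng.uniform(0.98, 1.02)
        trans = rng.uniform(-15.0, 15.0, size=3)
        out.append(SimilarityTransform(scale, rot, trans))
    return out


def simulate_longitudinal(
    config: SimulationConfig,
) -> tuple[list[SessionCloud], GroundTruth]:
    """Generate weekly observed session clouds plus the generating truth.

    The truth cloud is static except for the pre-death displacement ramps;
    each week's observed cloud is the surviving truth points mapped through
    that week's session transform with added centroid jitter, in shuffled
    row order.  Fiducial neurons never die.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    base = _base_cloud(config, rng)
    n = base.n
    ids = base.ids

    # hazard weights: death prefers sparse micro-neighbourhoods
    d3 = _mean_knn_distance(base.xyz, k=3)
    if config.sparsity_coupling > 0:
        w = d3**config.sparsity_coupling
        w = w / w[~base.fiducial].mean()
    else:
        w = np.ones(n)

    status = base.tangle.copy()
    tangle_onset = {int(i): 1 if status[i] else None for i in range(n)}
    death_week = np.zeros(n, dtype=int)  # 0 = persists through the experiment
    status_by_week = {1: status.copy()}

    for t in range(2, config.n_weeks + 1):
        alive = death_week == 0
        # deaths at week t use the tangle status entering the week
        hazard = np.where(status, config.hazard_tangle, config.hazard_nontangle)
        if config.hazard_change_week is not None and t >= config.hazard_change_week:
            hazard = hazard * config.hazard_change_factor
        p = np.clip(hazard * w, 0.0, 0.95)
        p[base.fiducial] = 0.0
        dies = alive & (rng.random(n) < p)
        death_week[dies] = t
        # new tangles among neurons still observed at week t
        survivors = death_week == 0
        new_tangle = survivors & ~status & (rng.random(n) < config.tangle_rate)
        status = status | new_tangle
        for i in np.flatnonzero(new_tangle):
            tangle_onset[int(i)] = t
        status_by_week[t] = status.copy()

    # pre-death neighbour displacement ramps
    transforms = (
        list(config.session_transforms)
        if config.session_transforms is not None
        else _default_transforms(config.n_weeks, rng)
    )
    jitter = {
        t: (
            rng.normal(0.0, config.jitter_sd, size=(n, 3))
            if config.jitter_sd > 0
            else np.zeros((n, 3))
        )
        for t in range(1, config.n_weeks + 1)
    }

    disp, ramp_neighbors = _solve_ramp_displacements(
        config, base, death_week, jitter, transforms
    )

    sessions = []
    for t in range(1, config.n_weeks + 1):
        present = (death_week == 0) | (death_week > t)
        pts = base.xyz[present] + disp[t][present]
        obs = transforms[t - 1].apply(pts) + jitter[t][present]
        order = rng.permutation(int(present.sum()))
        lo, hi = base.bounds
        corners = np.array(
            [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
        )
        mapped = transforms[t - 1].apply(corners)
        sessions.append(
            SessionCloud(
                xyz=obs[order],
                ids=ids[present][order],
                tangle=status_by_week[t][present][order],
                fiducial=base.fiducial[present][order],
                bounds=np.stack([mapped.min(axis=0), mapped.max(axis=0)]),
                week=t,
            )
        )

    fates = {}
    for i in range(n):
        if death_week[i] == 0:
            fates[int(i)] = {"fate": "persisted"}
        else:
            fates[int(i)] = {"fate": "disappeared", "death_week": int(death_week[i])}
    truth = GroundTruth(
        fates=fates,
        tangle_onset=tangle_onset,
        transforms=transforms,
        ramp_neighbors=ramp_neighbors,
        config=config,
    )
    return sessions, truth


def fate_agreement(tracks, truth: GroundTruth) -> float:
    """Fraction of unambiguous called fates matching the generating truth.

    Tracks with called fate ``ambiguous`` are excluded (they are also
    excluded from death counts downstream).
    """
    n_ok = 0
    n_tot = 0
    for tr in tracks:
        if tr.fate == "ambiguous":
            continue
        true = truth.fates.get(int(tr.track_id))
        if true is None:
            continue
        n_tot += 1
        if tr.fate == "persisted" and true["fate"] == "persisted":
            n_ok += 1
        elif (
            tr.fate == "disappeared"
            and true["fate"] == "disappeared"
            and tr.death_week == true["death_week"]
        ):
            n_ok += 1
    if n_tot == 0:
        raise ValueError("no comparable tracks")
    return n_ok / n_tot


# --------------------------------------------------------------------------
# snapshot cloud
# --------------------------------------------------------------------------


def generate_snapshot(config: SnapshotConfig) -> tuple[SessionCloud, dict]:
    """Single-time-point cloud with a planted locally-rarefied subpopulation.

    For each planted neuron, every point within a hole radius
    ``rho = (1 + enlargement_pct/100) * median(d3)`` is pushed radially
    outward into a thin shell just beyond ``rho``, so the focal neuron's
    3-NN distance lands near ``(1 + enlargement_pct/100)`` times the local
    average while total neuron count is preserved.  Returns the cloud and a
    truth dict with the planted ids and hole radius.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    bounds = config.bounds_array()
    xyz = _hard_core_points(config.n_neurons, bounds, config.min_separation, rng)
    n = len(xyz)
    n_enl = int(round(config.enlarged_fraction * n))

    enlarged_ids = np.empty(0, dtype=int)
    rho = float("nan")
    if n_enl > 0:
        d3 = _mean_knn_distance(xyz, k=3)
        rho = (1.0 + config.enlargement_pct / 100.0) * float(np.median(d3))
        lo, hi = bounds
        margin = 1.1 * rho
        interior = np.all((xyz >= lo + margin) & (xyz <= hi - margin), axis=1)
        # holes may partly overlap (the local-mean denominator is robust to
        # a nearby elevated d3), they only must not swallow each other's
        # centre; intruding pushed points are re-cleared below
        min_center_sep2 = (1.6 * rho) ** 2
        centers: list[int] = []
        center_xyz: list[np.ndarray] = []
        for idx in rng.permutation(n):
            if not interior[idx]:
                continue
            p = xyz[idx]
            if center_xyz and np.min(
                np.sum((np.asarray(center_xyz) - p) ** 2, axis=1)
            ) < min_center_sep2:
                continue
            centers.append(int(idx))
            center_xyz.append(p.copy())
            if len(centers) == n_enl:
                break
        if len(centers) < n_enl:
            raise PackingError(
                f"placed only {len(centers)}/{n_enl} rarefied centres; "
                "enlarged_fraction too high for the field size"
            )
        center_set = set(centers)
        for _ in range(3):  # clearing passes until no intruders remain
            tree = cKDTree(xyz)
            moved = 0
            for c in centers:
                for j in tree.query_ball_point(xyz[c], rho):
                    if j == c or j in center_set:
                        continue
                    v = xyz[j] - xyz[c]
                    r = float(np.linalg.norm(v))
                    if r == 0 or r >= rho:
                        continue
                    xyz[j] = xyz[c] + v * ((rho + 0.05 * r) / r)
                    moved += 1
            if moved == 0:
                break
        np.clip(xyz, bounds[0], bounds[1], out=xyz)
        enlarged_ids = np.sort(np.array(centers, dtype=int))

    tangle = rng.random(n) < config.tangle_fraction
    if n_enl > 0:
        tangle[enlarged_ids] = rng.random(n_enl) < config.tangle_on_enlarged_fraction

    cloud = SessionCloud(
        xyz=xyz,
        ids=np.arange(n, dtype=np.int64),
        tangle=tangle,
        fiducial=np.zeros(n, dtype=bool),
        bounds=bounds,
        week=1,
    )
    truth = {"enlarged_ids": [int(i) for i in enlarged_ids], "hole_radius_um": rho}
    return cloud, truth


# --------------------------------------------------------------------------
# voxel-level fixtures
# --------------------------------------------------------------------------


def render_stack(
    cloud: SessionCloud,
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM,
    psf_sd_um: float = 1.5,
) -> np.ndarray:
    """Render one Gaussian blob per nucleus into a ``(nz, ny, nx)`` stack.

    Stack dimensions follow ``bounds / voxel_size``; each blob peaks near
    1.0 at its nucleus voxel.  Intended only as a fixture for detector and
    object-filter tests, not as photorealistic microscopy.
    """
    dx, dy, dz = voxel_size_um
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValueError("voxel dimensions must be positive")
    lo, hi = cloud.bounds
    shape = tuple(
        int(np.ceil((hi[a] - lo[a]) / v)) for a, v in ((2, dz), (1, dy), (0, dx))
    )
    stack = np.zeros(shape, dtype=np.float32)
    if cloud.n == 0:
        return stack
    vox = np.array([dz, dy, dx])
    zyx = (cloud.xyz[:, ::-1] - lo[::-1]) / vox
    idx = np.clip(np.floor(zyx).astype(int), 0, np.array(shape) - 1)
    np.add.at(stack, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    sigma = (psf_sd_um / dz, psf_sd_um / dy, psf_sd_um / dx)
    stack = gaussian_filter(stack, sigma)
    peak = stack.max()
    if peak > 0:
        stack /= peak
    return stack


def save_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write a rendered stack as a multi-page TIFF (one page per z-plane)."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def load_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def detect_blobs(
    stack: np.ndarray,
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM,
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0),
    min_distance_um: float = 6.0,
    threshold_rel: float = 0.25,
) -> np.ndarray:
    """Detect blob centroids in a rendered stack, returned as (m, 3) x/y/z um.

    Peak detection with an anisotropy-aware footprint followed by a local
    centre-of-mass refinement; a deliberately simple detector used to close
    the render/detect round trip on synthetic fixtures.
    """
    dx, dy, dz = voxel_size_um
    fp_half = (
        max(1, int(min_distance_um / dz)),
        max(1, int(min_distance_um / dy)),
        max(1, int(min_distance_um / dx)),
    )
    footprint = np.ones(tuple(2 * h + 1 for h in fp_half), dtype=bool)
    peaks = peak_local_max(
        stack, footprint=footprint, threshold_rel=threshold_rel, exclude_border=False
    )
    vox = np.array([dz, dy, dx])
    win = np.array([1, 3, 3])
    out = []
    for pk in peaks:
        lo_i = np.maximum(pk - win, 0)
        hi_i = np.minimum(pk + win + 1, np.array(stack.shape))
        block = stack[lo_i[0] : hi_i[0], lo_i[1] : hi_i[1], lo_i[2] : hi_i[2]]
        zz, yy, xx = np.meshgrid(
            np.arange(lo_i[0], hi_i[0]),
            np.arange(lo_i[1], hi_i[1]),
            np.arange(lo_i[2], hi_i[2]),
            indexing="ij",
        )
        total = block.sum()
        com = np.array(
            [(zz * block).sum(), (yy * block).sum(), (xx * block).sum()]
        ) / total
        zyx_um = np.asarray(origin_um)[::-1] + (com + 0.5) * vox
        out.append(zyx_um[::-1])
    return np.array(out).reshape(-1, 3)
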