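"""Cortical-microstructure statistics on nucleus centroids.

Two bespoke statistics quantify the local rearrangement that precedes
neuron death:

* **Longitudinal neighbour-volume change** — for a focal neuron, the four
  nearest neurons that persist across all weeks define a tetrahedron; the
  percent change of its volume over the two weeks preceding the focal
  neuron's disappearance measures how far the neighbourhood has drifted
  apart.  An isotropic volume change of ``v`` percent is equivalent to a
  nearest-neighbour distance increase of
  ``d * ((1 + v/100)**(1/3) - 1)`` micrometres at baseline distance ``d``.

* **Single-snapshot local enlargement ratio** — each neuron's mean
  distance to its three nearest neighbours (``d3``) divided by the mean
  ``d3`` of all neurons within 100 um, minus one.  Neurons whose ratio
  exceeds 0.60 (strict) are flagged as sitting in enlarged microstructure
  and are at elevated risk of imminent death.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cloud import SessionCloud
from .tracking import NeuronTrack

#: Normalisation radius for the local enlargement ratio, micrometres.
DEFAULT_LOCAL_RADIUS_UM = 100.0

#: Enlargement cutoff (strict inequality) flagging disrupted microstructure.
ENLARGEMENT_THRESHOLD = 0.60

#: Minimum neighbourhood size for a defined local mean.
DEFAULT_MIN_LOCAL = 5


class InsufficientNeighborsError(ValueError):
    """Fewer neighbours available than the statistic requires."""


@dataclass
class MicrostructureRecord:
    """Per-neuron snapshot microstructure statistics."""

    neuron_id: int
    d3: float
    local_mean_d3: float | None
    enlargement: float | None
    n_local: int
    edge_flag: bool


@dataclass
class NeighborVolumeSeries:
    """Weekly tetrahedron volumes of a neuron's 4 persistent neighbours.

    ``flatness`` is the dimensionless shape quality ``V / L_rms^3`` per
    week (``L_rms`` the RMS edge length); a regular tetrahedron scores
    ~0.118 and coplanar vertices score 0.  Percent changes computed on a
    nearly flat baseline are dominated by measurement noise, so
    aggregations can use it as a degeneracy guard.
    """

    track_id: int
    neighbor_ids: tuple[int, int, int, int]
    volumes: dict  # week -> um^3
    flatness: dict | None = None  # week -> V / L_rms^3


# --------------------------------------------------------------------------
# k-NN distances and enlargement
# --------------------------------------------------------------------------


def mean_knn_distances(xyz: np.ndarray, k: int = 3) -> np.ndarray:
    """Mean distance from each point to its ``k`` nearest others (vectorised)."""
    xyz = np.asarray(xyz, dtype=float)
    if len(xyz) < k + 1:
        raise InsufficientNeighborsError(f"need at least {k + 1} points for k={k}")
    tree = cKDTree(xyz)
    d, _ = tree.query(xyz, k=k + 1)
    return d[:, 1:].mean(axis=1)


def knn_mean_distance(cloud: SessionCloud, focal_id: int, k: int = 3) -> float:
    """Mean distance from the focal neuron to its ``k`` nearest neighbours."""
    if cloud.n < k + 1:
        raise InsufficientNeighborsError(f"need at least {k + 1} neurons for k={k}")
    idx = np.flatnonzero(cloud.ids == focal_id)
    if len(idx) != 1:
        raise KeyError(f"focal id {focal_id} not found")
    d = np.linalg.norm(cloud.xyz - cloud.xyz[idx[0]], axis=1)
    d = np.delete(d, idx[0])
    return float(np.sort(d)[:k].mean())


def compute_microstructure(
    cloud: SessionCloud,
    radius_um: float = DEFAULT_LOCAL_RADIUS_UM,
    min_local: int = DEFAULT_MIN_LOCAL,
    k: int = 3,
) -> pd.DataFrame:
    """Snapshot microstructure table for every neuron in the cloud.

    Columns: ``neuron_id, d3, local_mean_d3, enlargement, n_local,
    edge_flag``.  The local mean excludes the focal neuron and uses the
    inclusive radius; records with fewer than ``min_local`` neighbours get
    a null enlargement rather than being dropped.  ``edge_flag`` marks
    neurons whose radius ball is clipped by the crop bounds.
    """
    d3 = mean_knn_distances(cloud.xyz, k=k)
    tree = cKDTree(cloud.xyz)
    neighborhoods = tree.query_ball_point(cloud.xyz, radius_um)
    lo, hi = cloud.bounds
    edge = np.any((cloud.xyz - lo < radius_um) | (hi - cloud.xyz < radius_um), axis=1)
    n_local = np.empty(cloud.n, dtype=int)
    local_mean = np.full(cloud.n, np.nan)
    for i, idx in enumerate(neighborhoods):
        m = len(idx) - 1  # query_ball_point includes the focal point
        n_local[i] = m
        if m >= min_local:
            local_mean[i] = (d3[idx].sum() - d3[i]) / m
    enlargement = d3 / local_mean - 1.0
    return pd.DataFrame(
        {
            "neuron_id": cloud.ids,
            "d3": d3,
            "local_mean_d3": local_mean,
            "enlargement": enlargement,
            "n_local": n_local,
            "edge_flag": edge,
        }
    )


def local_enlargement_ratio(
    cloud: SessionCloud,
    focal_id: int,
    radius_um: float = DEFAULT_LOCAL_RADIUS_UM,
    min_local: int = DEFAULT_MIN_LOCAL,
    k: int = 3,
) -> MicrostructureRecord:
    """Microstructure record of a single neuron (see compute_microstructure)."""
    table = compute_microstructure(cloud, radius_um=radius_um, min_local=min_local, k=k)
    row = table[table["neuron_id"] == focal_id]
    if row.empty:
        raise KeyError(f"focal id {focal_id} not found")
    r = row.iloc[0]
    return MicrostructureRecord(
        neuron_id=int(r["neuron_id"]),
        d3=float(r["d3"]),
        local_mean_d3=None if np.isnan(r["local_mean_d3"]) else float(r["local_mean_d3"]),
        enlargement=None if np.isnan(r["enlargement"]) else float(r["enlargement"]),
        n_local=int(r["n_local"]),
        edge_flag=bool(r["edge_flag"]),
    )


def flag_enlarged(
    records: pd.DataFrame, threshold: float = ENLARGEMENT_THRESHOLD
) -> set[int]:
    """Ids whose enlargement strictly exceeds ``threshold`` (nulls excluded)."""
    mask = records["enlargement"] > threshold
    return set(records.loc[mask.fillna(False), "neuron_id"].astype(int))


# --------------------------------------------------------------------------
# persistent-neighbour tetrahedron volumes
# --------------------------------------------------------------------------


def select_persistent_neighbors(
    track: NeuronTrack,
    tracks: list[NeuronTrack],
    m: int = 4,
    include_fiducials: bool = False,
) -> list[int]:
    """Ids of the ``m`` nearest persistent tracks at the focal's first week.

    The neighbour set is fixed at selection and reused for every week.
    Neighbours that die (or are ambiguous) are never selected; ties break
    on smaller track id.  Fiducial tracks are excluded by default: they
    anchor the session registration, so using them as displacement-
    sensitive vertices would couple the statistic to the alignment.
    """
    w0 = track.first_week
    cands = [
        t
        for t in tracks
        if t.fate == "persisted"
        and t.track_id != track.track_id
        and w0 in t.positions
        and (include_fiducials or not t.fiducial)
    ]
    if len(cands) < m:
        raise InsufficientNeighborsError(
            f"only {len(cands)} persistent neighbours available (need {m})"
        )
    focal = track.positions[w0]
    keyed = sorted(
        cands, key=lambda t: (float(np.linalg.norm(t.positions[w0] - focal)), t.track_id)
    )
    return [t.track_id for t in keyed[:m]]


def tetra_volume(vertices: np.ndarray) -> float:
    """Volume of the tetrahedron spanned by 4 points, ``|det| / 6`` (um^3).

    Coplanar vertices give 0 (with a warning).
    """
    v = np.asarray(vertices, dtype=float).reshape(4, 3)
    vol = abs(np.linalg.det(v[1:] - v[0])) / 6.0
    if vol == 0.0:
        warnings.warn("degenerate (coplanar) tetrahedron: volume 0", stacklevel=2)
    return float(vol)


def neighbor_volume_series(
    track: NeuronTrack, tracks: list[NeuronTrack], m: int = 4
) -> NeighborVolumeSeries:
    """Weekly tetrahedron volumes of the focal's fixed persistent neighbours."""
    if m != 4:
        raise ValueError("the neighbour tetrahedron requires exactly 4 vertices")
    nbr_ids = select_persistent_neighbors(track, tracks, m=m)
    by_id = {t.track_id: t for t in tracks}
    weeks = sorted(
        set.intersection(*(set(by_id[i].positions) for i in nbr_ids))
    )
    volumes, flatness = {}, {}
    for w in weeks:
        verts = np.stack([by_id[i].positions[w] for i in nbr_ids])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            volumes[w] = tetra_volume(verts)
        diffs = verts[:, None, :] - verts[None, :, :]
        iu = np.triu_indices(4, k=1)
        l_rms = float(np.sqrt((diffs[iu] ** 2).sum(axis=1).mean()))
        flatness[w] = volumes[w] / l_rms**3 if l_rms > 0 else 0.0
    return NeighborVolumeSeries(
        track_id=track.track_id,
        neighbor_ids=tuple(nbr_ids),
        volumes=volumes,
        flatness=flatness,
    )


def volume_change_percent(
    series: NeighborVolumeSeries,
    window: tuple[int, int] | None = None,
    death_week: int | None = None,
) -> float:
    """Percent change ``100 * (V_last - V_first) / V_first`` over a window.

    For a dying neuron pass ``death_week``: the window is then the two
    weeks preceding disappearance, ``(death_week - 2, death_week - 1)``.
    Otherwise ``window`` gives (first_week, last_week) explicitly; by
    default the full observed span is used.
    """
    if death_week is not None:
        window = (death_week - 2, death_week - 1)
    if window is None:
        wk = sorted(series.volumes)
        window = (wk[0], wk[-1])
    first, last = window
    if first not in series.volumes or last not in series.volumes:
        raise KeyError(f"weeks {window} not present in the volume series")
    if first >= last:
        raise ValueError("window must span at least 2 weekly volumes")
    v0 = series.volumes[first]
    if v0 == 0:
        raise ZeroDivisionError("first-window volume is zero")
    return float(100.0 * (series.volumes[last] - v0) / v0)


def volume_to_distance_equivalent(pct_change: float, baseline_d_um: float) -> float:
    """Distance increase (um) equivalent to a percent neighbour-volume change.

    Under isotropic scaling a volume factor ``1 + pct/100`` corresponds to
    a linear factor of its cube root, so the equivalent nearest-neighbour
    distance increase is ``baseline * ((1 + pct/100)**(1/3) - 1)``.
    """
    if pct_change <= -100.0:
        raise ValueError("pct_change must exceed -100")
    return float(baseline_d_um * ((1.0 + pct_change / 100.0) ** (1.0 / 3.0) - 1.0))


# --------------------------------------------------------------------------
# prospective risk of flagged neurons
# --------------------------------------------------------------------------


def risk_given_flag(
    tracks: list[NeuronTrack],
    flagged_ids: set[int] | list[int],
    horizon_weeks: int,
) -> tuple[float, float]:
    """(fraction of flagged neurons dying within the horizon, fold vs population).

    The horizon counts from each track's first observed week; ambiguous
    tracks are excluded from both numerator and denominator.  The fold is
    NaN (with a warning) when the flag set is empty or no neuron dies.
    """
    flagged_ids = set(int(i) for i in flagged_ids)
    usable = [t for t in tracks if t.fate != "ambiguous"]

    def died_within(t: NeuronTrack) -> bool:
        return (
            t.fate == "disappeared"
            and t.death_week is not None
            and t.death_week <= t.first_week + horizon_weeks
        )

    pop_n = len(usable)
    pop_dying = sum(died_within(t) for t in usable)
    flagged = [t for t in usable if t.track_id in flagged_ids]
    if not flagged:
        warnings.warn("empty flag set: risk undefined", stacklevel=2)
        return float("nan"), float("nan")
    frac = sum(died_within(t) for t in flagged) / len(flagged)
    if pop_n == 0 or pop_dying == 0:
        warnings.warn("no deaths in population: fold undefined", stacklevel=2)
        return float(frac), float("nan")
    fold = frac / (pop_dying / pop_n)
    return float(frac), float(fold)
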