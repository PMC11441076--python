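"""Linking nuclei across registered sessions and calling fates.

Sessions registered into a common frame are linked week-to-week with
mutual-nearest-neighbour matching under a hard distance gate (default
8 um, about one nucleus diameter and safely below the 12 um hard-core
separation).  A neuron's disappearance is called only when its absence
persists through the final session; a neuron that is transiently
unmatched but resighted later is flagged ``ambiguous`` and excluded from
all death counts.  Disappearances whose last known position lies within a
small margin of the crop boundary are likewise ambiguous, because exit
from the imaged field cannot be distinguished from death there.

Tangle status is assigned either from per-session tangle flags or from
detected tangle objects (connected components surviving the 100-voxel
size cutoff) lying within an association radius of the neuron.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.measure import regionprops

from .cloud import SessionCloud
from .imaging import DEFAULT_VOXEL_SIZE_UM, voxel_volume_um3

#: Minimum connected-component size for a tangle object, in voxels.
MIN_TANGLE_VOXELS = 100

#: Default matching gate in micrometres.
DEFAULT_GATE_UM = 8.0

#: Default neuron-tangle association radius in micrometres.
DEFAULT_ASSOCIATION_RADIUS_UM = 10.0

#: Guard band at the crop boundary, micrometres.  Tracks that ever come
#: this close to the bounds are censored (fate ``ambiguous``): there,
#: exit from the imaged overlap cannot be distinguished from death, and
#: censoring must apply symmetrically to dying and surviving neurons or
#: loss fractions are biased low.
DEFAULT_EDGE_MARGIN_UM = 2.0


@dataclass
class NeuronTrack:
    """One neuron's trajectory and fate across the imaging sessions."""

    track_id: int
    positions: dict  # week -> (3,) ndarray, um
    tangle_by_week: dict  # week -> bool (observed weeks only)
    fate: str  # "persisted" | "disappeared" | "ambiguous"
    death_week: int | None = None
    tangle_onset_week: int | None = None
    fiducial: bool = False

    @property
    def ever_tangled(self) -> bool:
        return self.tangle_onset_week is not None

    @property
    def first_week(self) -> int:
        return min(self.positions)


@dataclass
class TangleObject:
    """A size-filtered tau-tangle connected component."""

    centroid_um: np.ndarray
    voxel_count: int
    volume_um3: float
    first_week_seen: int = 1


def match_sessions(
    ref: SessionCloud, nxt: SessionCloud, gate_um: float = DEFAULT_GATE_UM
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mutual-nearest-neighbour pairs between two registered sessions.

    Returns ``(ref_idx, nxt_idx, dist)`` arrays for pairs whose distance is
    at most ``gate_um``; each nucleus participates in at most one pair.
    """
    if gate_um <= 0:
        raise ValueError("gate_um must be positive")
    if ref.n == 0 or nxt.n == 0:
        return np.empty(0, int), np.empty(0, int), np.empty(0)
    tree_ref = cKDTree(ref.xyz)
    tree_nxt = cKDTree(nxt.xyz)
    d_fwd, j_fwd = tree_nxt.query(ref.xyz, k=1)
    d_bwd, i_bwd = tree_ref.query(nxt.xyz, k=1)
    ref_idx = np.arange(ref.n)
    mutual = (i_bwd[j_fwd] == ref_idx) & (d_fwd <= gate_um)
    ri = ref_idx[mutual]
    return ri, j_fwd[mutual], d_fwd[mutual]


def build_tracks(
    sessions: list[SessionCloud],
    gate_um: float = DEFAULT_GATE_UM,
    edge_margin_um: float = DEFAULT_EDGE_MARGIN_UM,
) -> list[NeuronTrack]:
    """Chain week-to-week matches into tracks rooted at the first session.

    Requires sessions registered and cropped to common bounds, ordered by
    week.  Fate semantics:

    * ``persisted`` — matched in every session;
    * ``disappeared`` (with ``death_week``) — absent from the first
      unmatched session onward, never resighted;
    * ``ambiguous`` — unmatched at some week but a spatially compatible
      unassigned nucleus appears in a later week (transient invisibility),
      or the track ever comes within ``edge_margin_um`` of the crop
    boundary (edge censoring, applied symmetrically to all fates so that
    death counts on the interior are unbiased).
    """
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions")
    weeks = [s.week for s in sessions]
    if weeks != sorted(weeks):
        raise ValueError("sessions must be ordered by week")

    # consecutive-session links
    links: list[dict[int, int]] = []
    matched_next: list[np.ndarray] = []  # per gap: bool over next session's points
    for a, b in zip(sessions[:-1], sessions[1:]):
        ri, ni, _ = match_sessions(a, b, gate_um)
        links.append(dict(zip(ri.tolist(), ni.tolist())))
        m = np.zeros(b.n, dtype=bool)
        m[ni] = True
        matched_next.append(m)

    # per-session trees over points NOT matched from the previous session
    # (candidate resights of an earlier-lost neuron)
    unmatched_trees: list[tuple[cKDTree | None, int]] = [(None, 0)]
    for k in range(1, len(sessions)):
        free = ~matched_next[k - 1]
        n_free = int(free.sum())
        tree = cKDTree(sessions[k].xyz[free]) if n_free else None
        unmatched_trees.append((tree, n_free))

    lo, hi = sessions[0].bounds
    tracks: list[NeuronTrack] = []
    for i0 in range(sessions[0].n):
        positions = {weeks[0]: sessions[0].xyz[i0]}
        tangles = {weeks[0]: bool(sessions[0].tangle[i0])}
        cur = i0
        lost_at = None  # index into sessions of the first absence
        for k in range(1, len(sessions)):
            nxt = links[k - 1].get(cur)
            if nxt is None:
                lost_at = k
                break
            cur = nxt
            positions[weeks[k]] = sessions[k].xyz[cur]
            tangles[weeks[k]] = bool(sessions[k].tangle[cur])

        pos_arr = np.stack(list(positions.values()))
        near_edge = bool(
            np.any(pos_arr - lo < edge_margin_um)
            or np.any(hi - pos_arr < edge_margin_um)
        )
        if near_edge:
            fate, death_week = "ambiguous", None
        elif lost_at is None:
            fate, death_week = "persisted", None
        else:
            last_pos = positions[weeks[lost_at - 1]]
            resighted = False
            for k in range(lost_at, len(sessions)):
                tree, n_free = unmatched_trees[k]
                if tree is not None:
                    d, _ = tree.query(last_pos, k=1)
                    if d <= gate_um:
                        resighted = True
                        break
            if resighted:
                fate, death_week = "ambiguous", None
            else:
                fate, death_week = "disappeared", weeks[lost_at]

        onset = next((w for w in sorted(tangles) if tangles[w]), None)
        tracks.append(
            NeuronTrack(
                track_id=int(sessions[0].ids[i0]),
                positions=positions,
                tangle_by_week=tangles,
                fate=fate,
                death_week=death_week,
                tangle_onset_week=onset,
                fiducial=bool(sessions[0].fiducial[i0]),
            )
        )
    return tracks


# --------------------------------------------------------------------------
# tangle objects
# --------------------------------------------------------------------------


def filter_tangle_objects(
    labels: np.ndarray,
    voxel_size_um: tuple[float, float, float] | None = DEFAULT_VOXEL_SIZE_UM,
    min_voxels: int = MIN_TANGLE_VOXELS,
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0),
    week: int = 1,
) -> list[TangleObject]:
    """Size-filter labelled tangle components of a ``(nz, ny, nx)`` stack.

    Components smaller than ``min_voxels`` (default 100 voxels, ~49 um^3 at
    the native pitch) are discarded; retained objects carry their centroid
    in micrometres and voxel-geometry volume.
    """
    if voxel_size_um is None:
        raise ValueError("voxel size is required to filter tangle objects")
    vol1 = voxel_volume_um3(voxel_size_um)
    dx, dy, dz = voxel_size_um
    vox_zyx = np.array([dz, dy, dx])
    out = []
    for prop in regionprops(np.asarray(labels)):
        if prop.num_pixels < min_voxels:
            continue
        zyx_um = np.asarray(origin_um)[::-1] + (np.asarray(prop.centroid) + 0.5) * vox_zyx
        out.append(
            TangleObject(
                centroid_um=zyx_um[::-1],
                voxel_count=int(prop.num_pixels),
                volume_um3=float(prop.num_pixels * vol1),
                first_week_seen=week,
            )
        )
    return out


def assign_tangle_status(
    tracks: list[NeuronTrack],
    tangles_by_week: dict[int, list[TangleObject]],
    radius_um: float = DEFAULT_ASSOCIATION_RADIUS_UM,
) -> list[NeuronTrack]:
    """Set tangle onset to the first week a tangle lies within ``radius_um``.

    Tangle objects must be registered into the common frame.  An onset
    already recorded from per-session flags is kept if earlier.  Returns
    the same track objects, updated in place.
    """
    trees = {}
    for wk, objs in tangles_by_week.items():
        if objs:
            trees[wk] = cKDTree(np.stack([o.centroid_um for o in objs]))
    for tr in tracks:
        for wk in sorted(tr.positions):
            if tr.tangle_onset_week is not None and tr.tangle_onset_week <= wk:
                break
            tree = trees.get(wk)
            if tree is None:
                continue
            d, _ = tree.query(tr.positions[wk], k=1)
            if d <= radius_um:
                tr.tangle_onset_week = wk
                break
    return tracks


# --------------------------------------------------------------------------
# track table I/O
# --------------------------------------------------------------------------


def tracks_to_frame(tracks: list[NeuronTrack]) -> pd.DataFrame:
    weeks = sorted({w for t in tracks for w in t.positions})
    rows = []
    for t in tracks:
        row = {
            "track_id": t.track_id,
            "fate": t.fate,
            "death_week": t.death_week,
            "tangle_onset_week": t.tangle_onset_week,
            "ever_tangled": int(t.ever_tangled),
            "fiducial": int(t.fiducial),
        }
        for w in weeks:
            pos = t.positions.get(w)
            for axis, name in enumerate(("x", "y", "z")):
                row[f"{name}_w{w}"] = np.nan if pos is None else pos[axis]
        rows.append(row)
    return pd.DataFrame(rows)


def tracks_from_frame(frame: pd.DataFrame) -> list[NeuronTrack]:
    week_cols = sorted(
        {int(c.split("_w")[1]) for c in frame.columns if c.startswith("x_w")}
    )
    tracks = []
    for _, row in frame.iterrows():
        positions = {}
        for w in week_cols:
            xyz = np.array([row[f"x_w{w}"], row[f"y_w{w}"], row[f"z_w{w}"]])
            if not np.any(np.isnan(xyz)):
                positions[w] = xyz
        onset = row["tangle_onset_week"]
        onset = None if pd.isna(onset) else int(onset)
        death = row["death_week"]
        death = None if pd.isna(death) else int(death)
        tangle_by_week = {
            w: (onset is not None and w >= onset) for w in positions
        }
        tracks.append(
            NeuronTrack(
                track_id=int(row["track_id"]),
                positions=positions,
                tangle_by_week=tangle_by_week,
                fate=str(row["fate"]),
                death_week=death,
                tangle_onset_week=onset,
                fiducial=bool(row["fiducial"]),
            )
        )
    return tracks


def save_tracks(tracks: list[NeuronTrack], path: str | Path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False, float_format="%.6f")


def load_tracks(path: str | Path) -> list[NeuronTrack]:
    return tracks_from_frame(pd.read_csv(path))
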