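"""End-to-end orchestration: registration -> tracking -> statistics.

`run_pipeline` takes the raw per-week session clouds and produces a JSON-
serialisable report with registration residuals, fate tables, hazard
ratios, the tangle/fate chi-square, microstructure summaries and the
prospective risk of enlargement-flagged neurons.  `reference_report`
recomputes the worked-example numbers from the published summary counts
shipped in :mod:`neurofate.datasets`.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import datasets
from .cloud import SessionCloud
from .imaging import DEFAULT_VOXEL_SIZE_UM, voxel_volume_um3
from .microstructure import (
    DEFAULT_LOCAL_RADIUS_UM,
    ENLARGEMENT_THRESHOLD,
    InsufficientNeighborsError,
    compute_microstructure,
    flag_enlarged,
    neighbor_volume_series,
    risk_given_flag,
    volume_change_percent,
    volume_to_distance_equivalent,
)
from .registration import crop_to_overlap, register_sessions
from .survival import (
    FateTable,
    TwoByTwo,
    chi_square_2x2,
    hazard_ratio,
    loss_fraction,
    weekly_loss,
    weekly_loss_summary,
)
from .tracking import DEFAULT_GATE_UM, build_tracks


#: Minimum baseline tetra shape quality (V / L_rms^3) for a usable window.
#: A regular tetrahedron scores ~0.118, coplanar vertices 0.  Below ~0.02
#: the baseline volume of a typical neighbourhood (~30 um edges, ~0.5 um
#: centroid noise) is comparable to its own measurement noise, so the
#: percent change is dominated by the noisy denominator.
MIN_TETRA_FLATNESS = 0.02


def dying_volume_changes(
    tracks, min_prior_weeks: int = 2, min_flatness: float = MIN_TETRA_FLATNESS
) -> dict:
    """Neighbour-volume percent changes over each dying neuron's final window.

    Only dying neurons observed for at least ``min_prior_weeks`` weeks
    before disappearance and having 4 persistent neighbours enter; a
    matched final-2-week window is evaluated for persistent neurons.
    Windows whose baseline tetrahedron is nearly flat (shape quality below
    ``min_flatness``) are excluded as numerically unstable — the percent
    change of a near-degenerate volume is dominated by centroid noise —
    and counted in ``n_skipped``.
    """

    def window_change(t, window) -> float | None:
        try:
            series = neighbor_volume_series(t, tracks)
            if series.flatness is not None and series.flatness.get(window[0], 0.0) < min_flatness:
                return None
            return volume_change_percent(series, window=window)
        except (InsufficientNeighborsError, KeyError, ZeroDivisionError):
            return None

    dying, persistent_changes, skipped = [], [], 0
    last_week = max((max(t.positions) for t in tracks if t.positions), default=None)
    for t in tracks:
        if t.fate == "disappeared" and t.death_week is not None:
            if t.death_week - min_prior_weeks < t.first_week:
                continue
            c = window_change(t, (t.death_week - 2, t.death_week - 1))
            dying.append(c) if c is not None else (skipped := skipped + 1)
        elif t.fate == "persisted" and last_week is not None:
            c = window_change(t, (last_week - 1, last_week))
            persistent_changes.append(c) if c is not None else (skipped := skipped + 1)
    return {
        "dying_pct": dying,
        "persistent_pct": persistent_changes,
        "n_skipped": skipped,
    }


def run_pipeline(
    sessions: list[SessionCloud],
    gate_um: float = DEFAULT_GATE_UM,
    radius_um: float = DEFAULT_LOCAL_RADIUS_UM,
    enlargement_threshold: float = ENLARGEMENT_THRESHOLD,
    voxel_size_um=DEFAULT_VOXEL_SIZE_UM,
) -> dict:
    """Run registration, tracking and the bespoke statistics on raw sessions.

    Returns ``{"report": <dict>, "tracks": [...], "sessions": [...],
    "transforms": [...]}`` with the cropped registered sessions.
    """
    registered, transforms, reg_reports = register_sessions(
        sessions, voxel_size_um=voxel_size_um
    )
    cropped = crop_to_overlap(registered)
    tracks = build_tracks(cropped, gate_um=gate_um)

    table = FateTable.from_tracks(tracks)
    report: dict = {
        "registration": [r.to_dict() for r in reg_reports],
        "n_tracks": len(tracks),
        "n_ambiguous": sum(t.fate == "ambiguous" for t in tracks),
        "fate_counts": {
            label: {"n_total": g.n_total, "n_died": g.n_died}
            for label, g in table.groups.items()
        },
    }
    per_week = weekly_loss(table)
    report["weekly_loss_percent"] = {
        label: per_week[per_week["group"] == label]["percent"].tolist()
        for label in table.groups
    }
    if {"tangle", "non-tangle"} <= set(table.groups):
        report["loss_percent"] = {
            label: loss_fraction(table, label) for label in table.groups
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report["hazard_ratio_nontangle_vs_tangle"] = hazard_ratio(
                table, "non-tangle", "tangle"
            )
        try:
            stat, df = chi_square_2x2(
                TwoByTwo.from_fate_table(table, "non-tangle", "tangle")
            )
            report["chi_square"] = {"statistic": stat, "df": df}
        except ZeroDivisionError:
            report["chi_square"] = None  # no deaths observed: test undefined

    micro = compute_microstructure(cropped[0], radius_um=radius_um)
    flagged = flag_enlarged(micro, threshold=enlargement_threshold)
    horizon = max(t.death_week for t in tracks if t.death_week is not None) if any(
        t.fate == "disappeared" for t in tracks
    ) else len(sessions)
    frac, fold = (float("nan"), float("nan"))
    if flagged:
        frac, fold = risk_given_flag(tracks, flagged, horizon_weeks=horizon)
    report["microstructure"] = {
        "mean_d3_um": float(micro["d3"].mean()),
        "n_flagged_enlarged": len(flagged),
        "flagged_fraction_percent": 100.0 * len(flagged) / len(micro),
        "flagged_death_fraction": frac,
        "flagged_risk_fold": fold,
    }
    vols = dying_volume_changes(tracks)
    report["neighbor_volume"] = {
        "n_dying": len(vols["dying_pct"]),
        "dying_mean_pct": float(np.mean(vols["dying_pct"])) if vols["dying_pct"] else None,
        "persistent_mean_pct": (
            float(np.mean(vols["persistent_pct"])) if vols["persistent_pct"] else None
        ),
    }
    return {
        "report": report,
        "tracks": tracks,
        "sessions": cropped,
        "transforms": transforms,
    }


#: Published display values the reference report checks itself against,
#: as (key path, printed value, absolute tolerance at printed precision).
_PUBLISHED = [
    (("chi_square", "statistic"), 17.8, 0.05),
    (("loss_percent", "rtg4510_all"), 10.3, 0.05),
    (("loss_percent", "rtg4510_tangle"), 2.6, 0.05),
    (("loss_percent", "rtg4510_nontangle"), 11.6, 0.05),
    (("loss_percent", "rtg4510_control"), 0.5, 0.05),
    (("loss_percent", "thytau22"), 2.8, 0.05),
    (("loss_percent", "thytau22_wt"), 0.1, 0.05),
    (("human_enlarged_percent", "ad"), 2.00, 0.01),
    (("human_enlarged_percent", "control"), 0.49, 0.01),
    (("ever_tangled_total",), 235, 0),
    (("tangle_cutoff_volume_um3",), 49.0, 0.5),
    (("distance_equivalent_um",), 2.2, 0.05),
]


def reference_report() -> dict:
    """Worked-example numbers recomputed from the published summary counts."""
    d = datasets.RTG4510
    table = TwoByTwo(
        died_a=d["nontangle_died"],
        survived_a=d["nontangle_total"] - d["nontangle_died"],
        died_b=d["tangle_died"],
        survived_b=d["tangle_total"] - d["tangle_died"],
    )
    stat, df = chi_square_2x2(table)
    h = datasets.HUMAN_ITG
    m = datasets.MICROSTRUCTURE
    report = {
        "chi_square": {"statistic": stat, "df": df},
        "loss_percent": {
            "rtg4510_all": 100.0 * d["died"] / d["total"],
            "rtg4510_tangle": 100.0 * d["tangle_died"] / d["tangle_total"],
            "rtg4510_nontangle": 100.0 * d["nontangle_died"] / d["nontangle_total"],
            "rtg4510_control": 100.0
            * datasets.RTG4510_CONTROL["died"]
            / datasets.RTG4510_CONTROL["total"],
            "thytau22": 100.0 * datasets.THYTAU22["died"] / datasets.THYTAU22["total"],
            "thytau22_wt": 100.0
            * datasets.THYTAU22_WT["died"]
            / datasets.THYTAU22_WT["total"],
        },
        "human_enlarged_percent": {
            "ad": 100.0 * h["ad_enlarged"] / h["ad_neurons"],
            "control": 100.0 * h["control_enlarged"] / h["control_neurons"],
        },
        "cumulative_hazard_ratio_nontangle_vs_tangle": (
            (d["nontangle_died"] / d["nontangle_total"])
            / (d["tangle_died"] / d["tangle_total"])
        ),
        "ever_tangled_total": datasets.TANGLE_COUNTS["initial"]
        + datasets.TANGLE_COUNTS["new"],
        "tangle_cutoff_volume_um3": 100 * voxel_volume_um3(),
        "distance_equivalent_um": volume_to_distance_equivalent(
            m["dying_volume_increase_pct"], m["persisting_d3_um"]
        ),
    }
    checks = {}
    for path, printed, tol in _PUBLISHED:
        value = report
        for key in path:
            value = value[key]
        checks["/".join(path)] = {
            "computed": value,
            "published": printed,
            "pass": bool(abs(value - printed) <= tol),
        }
    report["published_value_checks"] = checks
    return report
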