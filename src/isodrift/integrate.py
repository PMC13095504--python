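"""Sequential integration: posterior × defoliation × retained trajectories.

The three independent lines of evidence — the isotopic posterior surface,
the defoliation (population-density) mask, and the retained wind
trajectories — are overlaid into a per-cell consensus score and ranked
candidate source regions:

* ``strict`` (default): score = posterior × 1[defoliated] × 1[≥1 retained
  trajectory released from the cell]; a zero in any layer zeroes the cell.
* ``soft``: score = posterior × normalized retained-release density ×
  normalized defoliation weight.

Candidate cells are aggregated into 4-connected regions and ranked by
total score (ties broken by first cell in row-major order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .assign import ProbabilitySurface
from .raster import Raster

__all__ = ["OriginReport", "candidate_origins", "event_summary"]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])

ADVISORY = ("no candidate region: consider earlier times and/or more distant "
            "source areas")


@dataclass
class OriginReport:
    """Ranked candidate natal-origin regions for one immigration event."""

    table: pd.DataFrame              # per-cell: row, col, posterior, defoliated, n_retained, score
    regions: list                    # ranked dicts: cells, score, centroid_lat/lon
    score: Raster
    status: str                      # "ok" | "no_candidates"
    warning: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def top_region_cells(self) -> set:
        return set(self.regions[0]["cells"]) if self.regions else set()


def _release_counts(trajectories, grid: Raster, retained_only: bool = True) -> np.ndarray:
    counts = np.zeros(grid.shape)
    for tr in trajectories:
        if retained_only and tr.verdict != "retained":
            continue
        if tr.release.cell is not None:
            r, c = tr.release.cell
        else:
            r, c = grid.cell_of(tr.release.lat, tr.release.lon)
        counts[r, c] += 1
    return counts


def candidate_origins(joint: ProbabilitySurface, trajectories,
                      defoliation: Raster, mode: str = "strict") -> OriginReport:
    """Overlay the evidence layers and rank candidate source regions."""
    if mode not in ("strict", "soft"):
        raise ValueError("mode must be 'strict' or 'soft'")
    grid = joint.probs
    grid.require_congruent(defoliation, "defoliation")
    unset = [tr for tr in trajectories if tr.verdict is None]
    if unset:
        raise ValueError("trajectories must carry verdicts (run apply_filters first)")

    post = joint.p()
    defol = np.where(np.isfinite(defoliation.values), defoliation.values, 0.0)
    retained = _release_counts(trajectories, grid, retained_only=True)

    if mode == "strict":
        score = post * (defol > 0) * (retained > 0)
    else:
        dens = retained / retained.max() if retained.max() > 0 else retained
        dw = defol / defol.max() if defol.max() > 0 else defol
        score = post * dens * dw

    rows, cols = np.nonzero(score > 0)
    table = pd.DataFrame({
        "row": rows, "col": cols,
        "posterior": post[rows, cols],
        "defoliated": (defol[rows, cols] > 0).astype(int),
        "n_retained": retained[rows, cols].astype(int),
        "score": score[rows, cols],
    })

    regions = []
    if len(rows):
        labels, n_lab = ndimage.label(score > 0, structure=_FOUR_CONN)
        for lab in range(1, n_lab + 1):
            cells = [tuple(map(int, rc)) for rc in np.argwhere(labels == lab)]
            cells.sort()                       # row-major, stable tie-breaking
            tot = float(score[labels == lab].sum())
            rr = np.array([c[0] for c in cells])
            cc = np.array([c[1] for c in cells])
            la, lo = grid.latlon_of(rr, cc)
            regions.append({"cells": cells, "score": tot,
                            "centroid_lat": float(la.mean()),
                            "centroid_lon": float(lo.mean())})
        regions.sort(key=lambda reg: (-reg["score"], reg["cells"][0]))
        status, warning = "ok", None
    else:
        status, warning = "no_candidates", ADVISORY

    n_retained_total = sum(1 for tr in trajectories if tr.verdict == "retained")
    if n_retained_total == 0 and warning is None:
        status, warning = "no_candidates", ADVISORY
    return OriginReport(table=table, regions=regions,
                        score=grid.like(score, units="consensus"),
                        status=status, warning=warning,
                        meta={"mode": mode, "n_trajectories": len(trajectories),
                              "n_retained": n_retained_total})


def _surface_stats(surface: ProbabilitySurface) -> dict:
    p = surface.probs.values[surface.valid]
    imax = int(np.argmax(p))
    rows, cols = np.nonzero(surface.valid)
    la, lo = surface.probs.latlon_of(rows[imax], cols[imax])
    return {
        "max_prob": float(p.max()),
        "mode_lat": float(la), "mode_lon": float(lo),
        "entropy_bits": float(-(p[p > 0] * np.log2(p[p > 0])).sum()),
        "n_valid_cells": int(p.size),
    }


def event_summary(report: OriginReport, surfaces, trajectories,
                  qa=None, event_meta=None) -> dict:
    """JSON-ready summary of one trap event.

    Includes per-individual and joint surface statistics, trajectory
    counts by verdict (conserving the released total), candidate regions
    with coordinates, and the advisory text when no candidate exists.
    """
    verdicts = {v: 0 for v in ("retained", "discarded_cold", "discarded_low",
                               "no_intersection")}
    for tr in trajectories:
        verdicts[tr.verdict] = verdicts.get(tr.verdict, 0) + 1
    summary = {
        "event": dict(event_meta or {}),
        "status": report.status,
        "advisory": report.warning,
        "individual_surfaces": [_surface_stats(s) for s in surfaces],
        "trajectories": {"released": len(trajectories), **verdicts},
        "candidate_regions": [
            {"rank": i + 1, "score": reg["score"], "n_cells": len(reg["cells"]),
             "centroid_lat": reg["centroid_lat"], "centroid_lon": reg["centroid_lon"]}
            for i, reg in enumerate(report.regions)
        ],
    }
    if qa is not None:
        summary["qa"] = {"odds_ratio": qa.odds_ratio, "bias": qa.bias}
    return summary
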