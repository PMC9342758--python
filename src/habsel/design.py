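"""Use-availability tables and the available-point ratio diagnostic.

For each individual, used telemetry rows are paired with ``ratio`` times as
many available rows sampled uniformly from that individual's availability
domain (study-area polygon at the 2nd-order scale, 95% kernel home range at
the 3rd).  The ratio diagnostic recomputes per-individual covariate means/SDs
of available points across candidate ratios and picks the smallest ratio at
which they have stabilized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .covariates import CovariateStack, extract

__all__ = [
    "DomainError",
    "RATIO_LADDER",
    "RatioDiagnostic",
    "sample_available",
    "build_table",
    "ratio_stabilization",
]

RATIO_LADDER = (1, 2, 5, 10, 20)


class DomainError(RuntimeError):
    """Rejection sampling from a degenerate (sliver) domain."""


@dataclass
class RatioDiagnostic:
    """Per-(ratio, covariate, individual) summary stats and the chosen ratio."""

    stats: pd.DataFrame  # columns: ratio, id, covariate, mean, sd
    selected_ratio: int
    epsilon: float
    stabilized: bool


def sample_available(domain, n: int, seed: int, min_acceptance: float = 1e-6) -> np.ndarray:
    """``n`` uniform points over a polygonal domain, by bounding-box rejection.

    Points exactly on the boundary count as inside.  Deterministic per seed.
    """
    if domain is None or domain.is_empty:
        raise DomainError("domain is empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = domain.bounds
    pts: list[np.ndarray] = []
    n_have = 0
    n_proposed = 0
    batch = max(2 * n, 256)
    while n_have < n:
        px = rng.uniform(x0, x1, size=batch)
        py = rng.uniform(y0, y1, size=batch)
        keep = shapely.intersects_xy(domain, px, py)
        n_proposed += batch
        n_have += int(keep.sum())
        pts.append(np.column_stack([px[keep], py[keep]]))
        if n_proposed >= 1_000_000 and n_have / n_proposed < min_acceptance:
            raise DomainError(
                f"acceptance rate {n_have / n_proposed:.2e} below "
                f"{min_acceptance:.0e}; domain is a degenerate sliver"
            )
    return np.concatenate(pts)[:n]


def build_table(
    used: pd.DataFrame,
    stack: CovariateStack,
    domains,
    ratio: int,
    scale: str,
    seed: int,
) -> pd.DataFrame:
    """Assemble one use-availability table at a single scale.

    ``used`` needs columns id, sex, x, y.  ``domains`` is either a single
    shapely geometry shared by all individuals or a mapping id -> geometry.
    Available rows inherit the individual's id and sex.  The returned frame
    has columns id, sex, label, scale, the stack covariates, and x, y;
    provenance (seed, ratio, scale) is stored in ``DataFrame.attrs``.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if scale not in ("study_area", "home_range"):
        raise ValueError("scale must be 'study_area' or 'home_range'")
    extent_box = shapely.box(*_extent_to_bounds(stack.extent))
    frames = []
    ids = list(dict.fromkeys(used["id"]))
    for i, ind_id in enumerate(ids):
        sub = used[used["id"] == ind_id]
        n_used = len(sub)
        if n_used == 0:
            raise ValueError(f"individual {ind_id} has 0 used points")
        sex = sub["sex"].iloc[0]
        dom = domains[ind_id] if isinstance(domains, dict) else domains
        dom = shapely.intersection(dom, extent_box)
        if dom.is_empty:
            raise DomainError(f"domain of {ind_id} does not intersect the raster")

        used_cov = extract(stack, sub[["x", "y"]].to_numpy())
        used_rows = used_cov.assign(
            id=ind_id, sex=sex, label="used", scale=scale,
            x=sub["x"].to_numpy(), y=sub["y"].to_numpy(),
        )
        avail_xy = sample_available(dom, ratio * n_used, seed=seed + 104729 * (i + 1))
        avail_cov = extract(stack, avail_xy)
        avail_rows = avail_cov.assign(
            id=ind_id, sex=sex, label="available", scale=scale,
            x=avail_xy[:, 0], y=avail_xy[:, 1],
        )
        frames.append(used_rows)
        frames.append(avail_rows)
    cov_names = list(stack.grids)
    table = pd.concat(frames, ignore_index=True)
    table = table[["id", "sex", "label", "scale"] + cov_names + ["x", "y"]]
    table.attrs.update({"seed": seed, "ratio": ratio, "scale": scale})
    return table


def _extent_to_bounds(extent):
    x0, y0, x1, y1 = extent
    return (x0, y0, x1, y1)


def ratio_stabilization(
    tables: dict[int, pd.DataFrame],
    epsilon: float = 0.05,
    abs_floor: float = 1.0,
    covariates: list[str] | None = None,
) -> RatioDiagnostic:
    """Pick the smallest ratio at which available-point stats stabilize.

    For every covariate and individual, the mean and SD of available rows are
    computed per ratio.  Ratio r qualifies when, against every larger ratio
    r', the relative change of both statistics is <= ``epsilon``.  The
    denominator is the larger-ratio value, floored by that covariate's
    available-point SD (a mean crossing zero — signed forest distance — would
    otherwise never look stable) and by ``abs_floor``.  If no ratio qualifies
    the largest is selected with ``stabilized=False``.
    """
    ratios = sorted(tables)
    if set(ratios) != set(RATIO_LADDER):
        raise ValueError(f"tables must cover ratios {RATIO_LADDER}")
    id_sets = {r: frozenset(tables[r]["id"]) for r in ratios}
    if len(set(id_sets.values())) != 1:
        raise ValueError("tables must cover the same individuals at every ratio")

    if covariates is None:
        fixed = {"id", "sex", "label", "scale", "x", "y"}
        covariates = [c for c in tables[ratios[0]].columns if c not in fixed]

    records = []
    for r in ratios:
        avail = tables[r][tables[r]["label"] == "available"]
        grp = avail.groupby("id", sort=True)[covariates].agg(["mean", "std"])
        for ind_id, row in grp.iterrows():
            for cov in covariates:
                records.append({
                    "ratio": r, "id": ind_id, "covariate": cov,
                    "mean": row[(cov, "mean")], "sd": row[(cov, "std")],
                })
    stats = pd.DataFrame.from_records(records)
    if not np.isfinite(stats[["mean", "sd"]].to_numpy()).all():
        raise ValueError("non-finite available-point statistics")

    wide = stats.pivot_table(
        index=["id", "covariate"], columns="ratio", values=["mean", "sd"]
    )
    selected = None
    for i, r in enumerate(ratios):
        ok = True
        for r_big in ratios[i + 1:]:
            sd_floor = wide[("sd", r_big)].to_numpy()
            for stat in ("mean", "sd"):
                a = wide[(stat, r)].to_numpy()
                b = wide[(stat, r_big)].to_numpy()
                denom = np.maximum(np.abs(b), np.maximum(sd_floor, abs_floor))
                rel = np.abs(a - b) / denom
                if (rel > epsilon).any():
                    ok = False
                    break
            if not ok:
                break
        if ok:
            selected = r
            break
    stabilized = selected is not None
    if selected is None:
        selected = ratios[-1]
    return RatioDiagnostic(
        stats=stats, selected_ratio=int(selected), epsilon=epsilon,
        stabilized=stabilized,
    )
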