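"""Independent reference implementations used only as test oracles.

Each routine deliberately takes a different computational route from the
package code it checks: brute-force likelihood grids, loop-based
sums-of-squares, and exhaustive enumeration of target-bin layouts.
"""

from __future__ import annotations

import numpy as np


def _grid_nll(locs, slopes, x, y):
    """Stable negative log-likelihood table (locations x slopes)."""
    ones = y == 1
    z = slopes[None, :, None] * (x[None, None, :] - locs[:, None, None])
    return (
        np.logaddexp(0.0, -z[:, :, ones]).sum(axis=2)
        + np.logaddexp(0.0, z[:, :, ~ones]).sum(axis=2)
    )


def grid_fit_aip(x, y, bounds, loc_step: float = 0.001, n_slopes: int = 120):
    """Brute-force likelihood-grid maximizer of the logistic choice model.

    Scans location over the offer bounds at ``loc_step`` resolution and
    slope over a log-spaced grid in [0.01, 50], then iteratively refines the
    slope grid around the best cell (rescanning a location window, since the
    profile-optimal location shifts with the slope); returns the location of
    the highest-likelihood cell.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    lo, hi = bounds
    locs = np.arange(lo, hi + 1e-12, loc_step)
    slopes = np.geomspace(0.01, 50.0, n_slopes)

    table = _grid_nll(locs, slopes, x, y)
    i, j = np.unravel_index(np.argmin(table), table.shape)
    best_loc, best_slope = float(locs[i]), float(slopes[j])
    for _ in range(2):
        window = locs[np.abs(locs - best_loc) <= 0.05 + 1e-12]
        fine_slopes = np.geomspace(max(0.01, best_slope / 2), min(50.0, best_slope * 2), 200)
        table = _grid_nll(window, fine_slopes, x, y)
        i, j = np.unravel_index(np.argmin(table), table.shape)
        best_loc, best_slope = float(window[i]), float(fine_slopes[j])
    return best_loc


def profile_location(x, y, slope, bounds, loc_step: float = 0.001):
    """Likelihood-maximizing location for a *fixed* slope (fine grid scan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    locs = np.arange(bounds[0], bounds[1] + 1e-12, loc_step)
    table = _grid_nll(locs, np.array([slope]), x, y)
    return float(locs[int(np.argmin(table[:, 0]))])


def mixed_anova_oracle(values: dict, group_of: dict):
    """Loop-based sums of squares for the 2x2 mixed design.

    ``values[subject] = (x_level1, x_level2)`` within-factor observations;
    ``group_of[subject]`` the between-group label.  Returns a dict of
    (ss, ss_error, df_error) per effect.
    """
    subjects = sorted(values)
    groups = sorted({group_of[s] for s in subjects})
    assert len(groups) == 2
    all_obs = [x for s in subjects for x in values[s]]
    grand = sum(all_obs) / len(all_obs)

    subj_mean = {s: sum(values[s]) / 2.0 for s in subjects}
    group_members = {g: [s for s in subjects if group_of[s] == g] for g in groups}
    group_mean = {g: sum(subj_mean[s] for s in group_members[g]) / len(group_members[g])
                  for g in groups}

    ss_between = 2.0 * sum(len(group_members[g]) * (group_mean[g] - grand) ** 2 for g in groups)
    ss_subj = 2.0 * sum((subj_mean[s] - group_mean[group_of[s]]) ** 2 for s in subjects)

    n_tot = len(subjects)
    level_mean = [sum(values[s][j] for s in subjects) / n_tot for j in (0, 1)]
    cell_mean = {
        (g, j): sum(values[s][j] for s in group_members[g]) / len(group_members[g])
        for g in groups
        for j in (0, 1)
    }
    ss_within_total = sum(
        (values[s][j] - subj_mean[s]) ** 2 for s in subjects for j in (0, 1)
    )
    ss_w = n_tot * sum((level_mean[j] - grand) ** 2 for j in (0, 1))
    ss_wb = sum(
        len(group_members[g])
        * (cell_mean[(g, j)] - level_mean[j] - group_mean[g] + grand) ** 2
        for g in groups
        for j in (0, 1)
    )
    ss_err = ss_within_total - ss_w - ss_wb
    return {
        "between": (ss_between, ss_subj, n_tot - 2),
        "within": (ss_w, ss_err, n_tot - 2),
        "interaction": (ss_wb, ss_err, n_tot - 2),
    }


def within_anova_oracle(values: dict):
    """Loop-based sums of squares for the fully within-subjects 2x2 design.

    ``values[subject] = {(a, b): x}`` over levels a, b in {0, 1}.
    """
    subjects = sorted(values)
    n = len(subjects)
    grand = sum(values[s][(a, b)] for s in subjects for a in (0, 1) for b in (0, 1)) / (4 * n)
    subj_mean = {s: sum(values[s].values()) / 4.0 for s in subjects}
    a_mean = [sum(values[s][(a, b)] for s in subjects for b in (0, 1)) / (2 * n) for a in (0, 1)]
    b_mean = [sum(values[s][(a, b)] for s in subjects for a in (0, 1)) / (2 * n) for b in (0, 1)]
    cell = {(a, b): sum(values[s][(a, b)] for s in subjects) / n for a in (0, 1) for b in (0, 1)}
    m_ia = {(s, a): (values[s][(a, 0)] + values[s][(a, 1)]) / 2.0 for s in subjects for a in (0, 1)}
    m_ib = {(s, b): (values[s][(0, b)] + values[s][(1, b)]) / 2.0 for s in subjects for b in (0, 1)}

    ss_a = 2.0 * n * sum((a_mean[a] - grand) ** 2 for a in (0, 1))
    ss_as = 2.0 * sum(
        (m_ia[(s, a)] - subj_mean[s] - a_mean[a] + grand) ** 2 for s in subjects for a in (0, 1)
    )
    ss_b = 2.0 * n * sum((b_mean[b] - grand) ** 2 for b in (0, 1))
    ss_bs = 2.0 * sum(
        (m_ib[(s, b)] - subj_mean[s] - b_mean[b] + grand) ** 2 for s in subjects for b in (0, 1)
    )
    ss_ab = n * sum((cell[(a, b)] - a_mean[a] - b_mean[b] + grand) ** 2 for a in (0, 1) for b in (0, 1))
    ss_abs = sum(
        (
            values[s][(a, b)]
            - m_ia[(s, a)]
            - m_ib[(s, b)]
            + subj_mean[s]
            - cell[(a, b)]
            + a_mean[a]
            + b_mean[b]
            - grand
        )
        ** 2
        for s in subjects
        for a in (0, 1)
        for b in (0, 1)
    )
    return {
        "A": (ss_a, ss_as, n - 1),
        "B": (ss_b, ss_bs, n - 1),
        "interaction": (ss_ab, ss_abs, n - 1),
    }


def consistent_short_bins(positions, lo: int = 7, n_bins: int = 10):
    """Enumerate which short-bin placements could have generated a target set.

    For each candidate slot of the length-1 bin, rebuild the bin boundaries
    and check that the k-th position falls inside the k-th bin.
    """
    out = []
    for short in range(n_bins):
        start = lo
        ok = True
        for b in range(n_bins):
            length = 1 if b == short else 2
            if not (start <= positions[b] < start + length):
                ok = False
                break
            start += length
        if ok:
            out.append(short)
    return out
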