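"""BF-aligned population tuning curves, fitted and unfitted.

Fitted curves: each included unit's Gaussian is evaluated on a common
octave grid centred on that unit's *pre-pairing* BF, then averaged
across units — so the pre-phase population curve peaks at 0 by
construction and any systematic post-pairing BF shift appears as a
displaced post-curve peak.

Unfitted curves avoid the fit entirely: the unit's intensity-averaged
normalized profile is shifted so its pre-pairing argmax sits at step 0
on the quarter-octave step axis, and units are averaged where they
overlap.  Paired t-tests on the unfitted BF (in grid steps) and on the
normalized peak amplitude ask whether either changed after pairing
without any model in the loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import PosthocRow, posthoc_paired

__all__ = [
    "PopulationCurve",
    "align_fitted_curves",
    "unfitted_bf",
    "align_unfitted_curves",
    "test_bf_shift",
    "plot_population_curves",
]

#: Common octave grid for fitted population curves: -2..+2 oct in 0.05 steps.
FITTED_GRID_OCT = np.round(np.arange(-40, 41) * 0.05, 10)


@dataclass
class PopulationCurve:
    """Mean +/- SEM response versus octave (or grid-step) offset from pre-BF."""

    x_oct: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_units: int
    phase: str
    group: str
    n_contributing: np.ndarray = None  # per-point unit counts (unfitted curves)

    def peak_offset(self) -> float:
        """Location of the curve maximum on the aligned axis."""
        return float(self.x_oct[int(np.argmax(self.mean))])

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"x_oct": self.x_oct, "mean": self.mean,
                           "sem": self.sem})
        df["n_units"] = self.n_units
        if self.n_contributing is not None:
            df["n_contributing"] = self.n_contributing
        df["phase"] = self.phase
        df["group"] = self.group
        return df


def _sem(values: np.ndarray, axis=0) -> np.ndarray:
    n = values.shape[axis]
    return np.std(values, axis=axis, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(
        values.shape[1 - axis])


def align_fitted_curves(records, group: str, phase: str,
                        grid_oct: np.ndarray = FITTED_GRID_OCT) -> PopulationCurve:
    """Average fitted Gaussians across a group, aligned to each unit's pre-BF.

    ``records`` is an iterable of :class:`~tuneplast.stats.UnitRecord`;
    ``group`` is "drug/side" (e.g. "tPA/above") or "all".
    """
    curves = []
    for rec in _select(records, group):
        fit = rec.fit_pre if phase == "pre" else rec.fit_post
        x_abs = rec.fit_pre.bf_oct + grid_oct  # centre on the PRE-pairing BF
        curves.append(fit.predict(x_abs))
    if len(curves) < 1:
        raise ValueError(f"no included units in group {group!r}")
    curves = np.asarray(curves)
    return PopulationCurve(
        x_oct=np.asarray(grid_oct, float), mean=curves.mean(axis=0),
        sem=_sem(curves), n_units=len(curves), phase=phase, group=group,
    )


def _select(records, group: str):
    sel = []
    for rec in records:
        if not rec.included:
            continue
        if group == "all" or f"{rec.drug}/{rec.side}" == group:
            sel.append(rec)
    return sel


def unfitted_bf(profile) -> int:
    """Index of the maximum of an intensity-averaged profile.

    Ties are broken toward the lower frequency (np.argmax's first-max
    rule) for determinism.  A constant profile has no BF and raises.
    """
    y = np.asarray(profile, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant profile has no best frequency")
    return int(np.argmax(y))


def align_unfitted_curves(profiles_pre: dict, profiles_by_phase: dict, group_units,
                          phase: str, group: str = "",
                          min_coverage: float = 0.5) -> PopulationCurve:
    """Average normalized profiles on the quarter-octave step axis.

    Each unit's profile is shifted so its *pre-pairing* unfitted BF sits
    at step 0.  The averaged curve is truncated to steps where at least
    ``min_coverage`` of the units contribute, avoiding edge artifacts
    from the shifting; per-step contribution counts are returned.

    Parameters
    ----------
    profiles_pre : dict unit_id -> pre-phase profile (for alignment)
    profiles_by_phase : dict unit_id -> profile of the requested phase
    group_units : unit ids to include
    """
    group_units = list(group_units)
    if not group_units:
        raise ValueError(f"no units in group {group!r}")
    n_freq = len(next(iter(profiles_pre.values())))
    steps = np.arange(-(n_freq - 1), n_freq)  # all possible aligned offsets
    stack = np.full((len(group_units), steps.size), np.nan)
    for i, uid in enumerate(group_units):
        bf_idx = unfitted_bf(profiles_pre[uid])
        y = np.asarray(profiles_by_phase[uid], dtype=float)
        lo = (n_freq - 1) - bf_idx  # step index where this unit's freq 0 lands
        stack[i, lo:lo + n_freq] = y
    counts = np.sum(~np.isnan(stack), axis=0)
    keep = counts >= max(2, min_coverage * len(group_units))
    if not np.any(keep):
        raise ValueError("no overlap between aligned profiles")
    stack = stack[:, keep]
    mean = np.nanmean(stack, axis=0)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(stack, axis=0, ddof=1)
    sem = sd / np.sqrt(counts[keep])
    return PopulationCurve(
        x_oct=steps[keep].astype(float), mean=mean, sem=sem,
        n_units=len(group_units), phase=phase, group=group,
        n_contributing=counts[keep],
    )


def test_bf_shift(profiles_pre: dict, profiles_post: dict, group_units,
                  group: str = "") -> dict[str, PosthocRow]:
    """Paired tests for post-pairing change in unfitted BF and peak amplitude.

    BF is the argmax of the intensity-averaged normalized profile, in
    quarter-octave grid steps; amplitude is the profile value at that
    argmax.  Returns ``{"bf": PosthocRow, "amplitude": PosthocRow}``
    with diff = pre - post (negative BF diff = upward shift).
    """
    group_units = list(group_units)
    if len(group_units) < 2:
        raise ValueError("need at least 2 units to test a BF shift")
    bf_pre, bf_post, amp_pre, amp_post = [], [], [], []
    for uid in group_units:
        i_pre = unfitted_bf(profiles_pre[uid])
        i_post = unfitted_bf(profiles_post[uid])
        bf_pre.append(i_pre)
        bf_post.append(i_post)
        amp_pre.append(float(np.asarray(profiles_pre[uid])[i_pre]))
        amp_post.append(float(np.asarray(profiles_post[uid])[i_post]))
    return {
        "bf": posthoc_paired(bf_pre, bf_post,
                             comparison=f"{group} unfitted BF (steps): pre vs post"),
        "amplitude": posthoc_paired(amp_pre, amp_post,
                                    comparison=f"{group} normalized peak: pre vs post"),
    }


def plot_population_curves(curves, path, x_label="octaves re pre-pairing BF"):
    """Render a grid of population curves (pre black, post colored) to file.

    ``curves`` is a tidy frame as produced by concatenating
    :meth:`PopulationCurve.to_frame` rows over groups and phases, e.g.
    the ``fitted_curves``/``unfitted_curves`` tables of a pipeline run.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(dict.fromkeys(curves["group"]))
    fig, axes = plt.subplots(1, len(groups), figsize=(4 * len(groups), 3.2),
                             sharey=True, squeeze=False)
    for ax, group in zip(axes[0], groups):
        for phase, color in (("pre", "black"), ("post", "tab:red")):
            sub = curves[(curves["group"] == group) & (curves["phase"] == phase)]
            if sub.empty:
                continue
            ax.plot(sub["x_oct"], sub["mean"], color=color, label=phase)
            ax.plot(sub["x_oct"], sub["mean"] + sub["sem"], color=color,
                    ls="--", lw=0.8)
            ax.plot(sub["x_oct"], sub["mean"] - sub["sem"], color=color,
                    ls="--", lw=0.8)
        ax.axvline(0.0, color="gray", lw=0.5)
        ax.set_title(group)
        ax.set_xlabel(x_label)
    axes[0, 0].set_ylabel("response")
    axes[0, 0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
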