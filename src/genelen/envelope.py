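"""Shuffle null envelope for the length curve and window significance calls.

The null hypothesis is that expression change is independent of gene
length. It is emulated by randomly re-pairing the per-gene statistic with
the per-gene lengths (a uniform random permutation of the pairing, which
preserves both marginal multisets), recomputing the sliding-window curve,
and repeating; the pointwise 2.5%/97.5% quantiles across iterations form a
95% null envelope. Windows of the observed curve falling strictly outside
the envelope are flagged.

The default re-pairing samples without replacement (a permutation); a
with-replacement resampling variant is available behind a flag for
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .curves import _sort_by_length, _window_means, sliding_windows

N_ITERATIONS_DEFAULT = 100
CI_DEFAULT = 0.95


@dataclass
class BootstrapEnvelope:
    """Pointwise null quantile band for a binned curve.

    ``table`` has one row per window: ``window_start``, ``mean_length``,
    ``lower``, ``upper``. The iteration count, CI level, seed and
    resampling mode are recorded alongside.
    """

    table: pd.DataFrame
    n_iterations: int
    ci: float
    seed: int | None
    with_replacement: bool = False

    def __post_init__(self) -> None:
        if (self.table["lower"] > self.table["upper"]).any():
            raise ValueError("envelope lower bound exceeds upper bound")


def permute_length_assignment(profile: pd.DataFrame,
                              rng: np.random.Generator) -> pd.DataFrame:
    """Randomly re-pair per-gene statistics with gene lengths.

    Returns a profile in which each (gene, length) keeps its row but the
    (logfc, variance) pairs are drawn as a uniform random permutation, so
    both the multiset of statistics and the multiset of lengths are
    preserved exactly.
    """
    perm = rng.permutation(len(profile))
    out = profile.copy()
    cols = [c for c in ("logfc", "variance") if c in profile.columns]
    out[cols] = profile[cols].to_numpy()[perm]
    return out


def bootstrap_envelope(profile: pd.DataFrame, window: int = 200,
                       step: int = 40,
                       n_iterations: int = N_ITERATIONS_DEFAULT,
                       ci: float = CI_DEFAULT,
                       seed: int | None = None,
                       with_replacement: bool = False) -> BootstrapEnvelope:
    """Null envelope of the length curve from shuffled length pairings.

    Each iteration re-pairs the statistic with the lengths, recomputes the
    window means over the same length-sorted window grid, and the pointwise
    ``(1-ci)/2`` and ``1-(1-ci)/2`` empirical quantiles (linear
    interpolation between order statistics) across iterations form the
    envelope.
    """
    if not 0 < ci < 1:
        raise ValueError("ci must be in (0, 1)")
    if n_iterations < 20 and ci >= 0.95:
        warnings.warn(
            f"{n_iterations} iterations give unstable {ci:.0%} quantiles",
            stacklevel=2,
        )
    order = _sort_by_length(profile["length"])
    values = profile["logfc"].loc[order].to_numpy(dtype=float)
    lengths = profile["length"].loc[order].to_numpy(dtype=float)
    n = values.size
    starts = sliding_windows(n, window, step)
    rng = np.random.default_rng(seed)
    means = np.empty((n_iterations, starts.size))
    for i in range(n_iterations):
        if with_replacement:
            idx = rng.integers(0, n, size=n)
        else:
            idx = rng.permutation(n)
        means[i] = _window_means(values[idx], starts, window)
    alpha = (1.0 - ci) / 2.0
    # Weibull plotting position: at 100 iterations the 2.5%/97.5% bounds
    # interpolate between the 2nd-3rd and 98th-99th order statistics, so a
    # null draw escapes each side with probability ~alpha.
    lower, upper = np.quantile(means, [alpha, 1.0 - alpha], axis=0,
                               method="weibull")
    table = pd.DataFrame({
        "window_start": starts,
        "mean_length": _window_means(lengths, starts, window),
        "lower": lower,
        "upper": upper,
    })
    return BootstrapEnvelope(table, n_iterations, ci, seed, with_replacement)


def _check_windows(curve: pd.DataFrame, env: BootstrapEnvelope) -> None:
    if not np.array_equal(curve["window_start"].to_numpy(),
                          env.table["window_start"].to_numpy()):
        raise ValueError("curve and envelope cover different windows")


def call_significant_windows(curve: pd.DataFrame,
                             env: BootstrapEnvelope) -> pd.Series:
    """Flag each window as 'below', 'inside' or 'above' the envelope.

    Inequalities are strict: a window mean exactly on a bound is 'inside'.
    """
    _check_windows(curve, env)
    stat = curve["mean_stat"].to_numpy()
    flags = np.where(stat > env.table["upper"].to_numpy(), "above",
                     np.where(stat < env.table["lower"].to_numpy(),
                              "below", "inside"))
    return pd.Series(flags, index=curve.index, name="flag")


def envelope_distance(curve: pd.DataFrame,
                      env: BootstrapEnvelope) -> tuple[pd.Series, float]:
    """Signed per-window exceedance beyond the envelope, and its mean.

    Positive above the upper bound, negative below the lower bound, zero
    inside. The summary is the mean over all windows and measures how far
    the observed curve escapes the null band.
    """
    _check_windows(curve, env)
    stat = curve["mean_stat"].to_numpy()
    upper = env.table["upper"].to_numpy()
    lower = env.table["lower"].to_numpy()
    dist = np.where(stat > upper, stat - upper,
                    np.where(stat < lower, stat - lower, 0.0))
    series = pd.Series(dist, index=curve.index, name="distance")
    return series, float(series.mean())


def write_envelope_tsv(env: BootstrapEnvelope, curve: pd.DataFrame,
                       flags: pd.Series, path,
                       metadata: Mapping[str, object] | None = None) -> None:
    """Serialize envelope + observed curve + flags as annotated TSV."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# n_iterations={env.n_iterations} ci={env.ci} "
                 f"seed={env.seed} with_replacement={env.with_replacement}\n")
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        out = env.table.rename(columns={"mean_length": "mean_length_bp"})
        out = out.assign(observed=curve["mean_stat"].to_numpy(),
                         flag=flags.to_numpy())
        out.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_envelope_tsv(path) -> tuple[BootstrapEnvelope, pd.DataFrame]:
    """Read an envelope TSV back into the envelope and the observed curve."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    for item in first.lstrip("# ").split():
        key, _, val = item.partition("=")
        meta[key] = val
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.rename(columns={"mean_length_bp": "mean_length"})
    seed = None if meta.get("seed") == "None" else int(meta["seed"])
    env = BootstrapEnvelope(
        df[["window_start", "mean_length", "lower", "upper"]],
        n_iterations=int(meta["n_iterations"]),
        ci=float(meta["ci"]),
        seed=seed,
        with_replacement=meta.get("with_replacement") == "True",
    )
    curve = df[["window_start", "mean_length"]].assign(
        mean_stat=df["observed"])
    return env, curve
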