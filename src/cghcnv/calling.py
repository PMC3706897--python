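"""Per-fragment CNV calling with a two-component Gaussian mixture.

For each genotype, the distribution of fragment-mean log2(sample/reference)
ratios is modelled as a mixture of a tight null component (unchanged copy
number, centred near 0) and a broad two-sided variant component. The
expectation-maximization fit is deterministic: the null component is
initialized at (median, MAD^2) and the variant component from the values
beyond +-0.9. A fragment is called when its posterior probability of
belonging to the variant component exceeds 0.95 AND its |log2 ratio| exceeds
0.9 (a near two-fold intensity change); the call direction comes from the
ratio's sign (UpCNV vs DownCNV/PAV — the array cannot distinguish a strong
copy loss from complete absence).

Runs of same-class called fragments that are consecutive in a contig's
fragment order merge into CNV events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UP = "UpCNV"
DOWN = "DownCNV/PAV"

CALL_COLUMNS = ["fragment_id", "genotype", "class", "log2", "posterior"]


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture fit; component 1 is the variant."""

    pi: float  # mixing proportion of the variant component
    mu_variant: float
    sigma_variant: float
    mu_null: float
    sigma_null: float
    posteriors: np.ndarray  # P(variant | value), aligned to the input
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0


def _normal_logpdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return -0.5 * np.log(2 * np.pi * sigma**2) - 0.5 * ((x - mu) / sigma) ** 2


def fit_two_component_em(
    values: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
    min_sigma: float = 1e-4,
    init: tuple | None = None,
    seed: int | None = None,
) -> MixtureFit:
    """Deterministic EM fit of null + variant Gaussian components.

    ``init`` may override the starting parameters as
    (pi, mu_variant, sigma_variant, mu_null, sigma_null). ``seed`` is
    accepted for interface uniformity; the default initialization is
    deterministic and does not consume randomness.

    Degenerate inputs (near-zero spread) return a null-only fit with all
    posteriors 0 and a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("values must be a non-empty 1-d array")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")

    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if init is not None:
        pi, mu1, s1, mu0, s0 = init
    else:
        mu0, s0 = med, max(1.4826 * mad, min_sigma)
        tails = x[np.abs(x) > 0.9]
        if len(tails) >= 2:
            pi = len(tails) / len(x)
            mu1 = float(tails.mean())
            s1 = max(float(tails.std()), 2 * s0, min_sigma)
        else:
            pi, mu1, s1 = 0.01, mu0 - 2.0, max(4 * s0, 0.5)

    if np.ptp(x) < 10 * min_sigma:
        warnings.warn("degenerate (constant) input: null-only fit", stacklevel=2)
        return MixtureFit(
            pi=0.0,
            mu_variant=mu0,
            sigma_variant=min_sigma,
            mu_null=mu0,
            sigma_null=min_sigma,
            posteriors=np.zeros(len(x)),
            loglik_trace=[],
            converged=True,
            n_iter=0,
        )

    trace: list[float] = []
    resp = np.zeros(len(x))
    for it in range(1, max_iter + 1):
        # E step
        lp1 = np.log(max(pi, 1e-300)) + _normal_logpdf(x, mu1, s1)
        lp0 = np.log(max(1 - pi, 1e-300)) + _normal_logpdf(x, mu0, s0)
        m = np.maximum(lp1, lp0)
        denom = m + np.log(np.exp(lp1 - m) + np.exp(lp0 - m))
        resp = np.exp(lp1 - denom)
        ll = float(denom.sum())
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            break
        # M step
        w1 = resp.sum()
        w0 = len(x) - w1
        pi = w1 / len(x)
        if w1 > 1e-10:
            mu1 = float((resp * x).sum() / w1)
            s1 = max(float(np.sqrt((resp * (x - mu1) ** 2).sum() / w1)), min_sigma)
        if w0 > 1e-10:
            mu0 = float(((1 - resp) * x).sum() / w0)
            s0 = max(float(np.sqrt(((1 - resp) * (x - mu0) ** 2).sum() / w0)), min_sigma)

    # orientation: the variant component has the mean farther from 0
    # (tie-broken by the larger variance)
    if (abs(mu0), s0) > (abs(mu1), s1):
        pi, mu1, s1, mu0, s0 = 1 - pi, mu0, s0, mu1, s1
        resp = 1 - resp
    return MixtureFit(
        pi=float(pi),
        mu_variant=mu1,
        sigma_variant=s1,
        mu_null=mu0,
        sigma_null=s0,
        posteriors=resp,
        loglik_trace=trace,
        converged=it < max_iter,
        n_iter=it,
    )


def call_cnvs(
    fit: MixtureFit,
    signals: pd.DataFrame,
    p_min: float = 0.95,
    min_abs_log2: float = 0.9,
) -> pd.DataFrame:
    """Emit a CNV call for every fragment with posterior > p_min and
    |log2| > min_abs_log2 (both strict); class is the ratio's sign.

    ``signals``: DataFrame (fragment_id, genotype, log2) for one genotype,
    row-aligned with ``fit.posteriors``.
    """
    if len(signals) != len(fit.posteriors):
        raise ValueError("signals and fit posteriors are not aligned")
    vals = signals["log2"].to_numpy(float)
    mask = (fit.posteriors > p_min) & (np.abs(vals) > min_abs_log2)
    out = signals.loc[mask, ["fragment_id", "genotype", "log2"]].copy()
    out["posterior"] = fit.posteriors[mask]
    out["class"] = np.where(out["log2"] > 0, UP, DOWN)
    return out[CALL_COLUMNS].reset_index(drop=True)


def call_genotypes(
    signals: pd.DataFrame, p_min: float = 0.95, min_abs_log2: float = 0.9, **em_kwargs
) -> tuple[pd.DataFrame, dict[str, MixtureFit]]:
    """Fit the mixture per genotype over all its fragments and call CNVs."""
    calls = []
    fits: dict[str, MixtureFit] = {}
    for genotype, sub in signals.groupby("genotype", sort=False):
        sub = sub.reset_index(drop=True)
        fit = fit_two_component_em(sub["log2"].to_numpy(float), **em_kwargs)
        fits[genotype] = fit
        calls.append(call_cnvs(fit, sub, p_min=p_min, min_abs_log2=min_abs_log2))
    frame = (
        pd.concat(calls, ignore_index=True)
        if calls
        else pd.DataFrame(columns=CALL_COLUMNS)
    )
    return frame, fits


def merge_consecutive_events(calls: pd.DataFrame, fragments: pd.DataFrame) -> pd.DataFrame:
    """Merge runs of same-class calls on consecutive contig fragments.

    Adjacency is defined by the fragment order on each contig. Singleton
    runs are kept (n_fragments = 1) so that multi-fragment events can be
    filtered downstream.

    Returns a DataFrame (contig, genotype, class, fragment_ids, n_fragments,
    start, end).
    """
    known = set(fragments["fragment_id"])
    unknown = set(calls["fragment_id"]) - known
    if unknown:
        raise ValueError(f"calls reference unknown fragments: {sorted(unknown)[:5]}")
    order = fragments.sort_values(["contig", "start"])
    call_map = {
        (rec["fragment_id"], rec["genotype"]): rec["class"]
        for rec in calls.to_dict("records")
    }
    events = []
    for genotype in calls["genotype"].unique():
        for contig, sub in order.groupby("contig", sort=False):
            run: list = []
            run_class = None

            def flush(contig=None, genotype=None, run=None, run_class=None):
                if run:
                    events.append(
                        {
                            "contig": contig,
                            "genotype": genotype,
                            "class": run_class,
                            "fragment_ids": [f.fragment_id for f in run],
                            "n_fragments": len(run),
                            "start": int(run[0].start),
                            "end": int(run[-1].end),
                        }
                    )

            for frag in sub.itertuples(index=False):
                klass = call_map.get((frag.fragment_id, genotype))
                if klass is None:
                    flush(contig, genotype, run, run_class)
                    run, run_class = [], None
                elif klass == run_class:
                    run.append(frag)
                else:
                    flush(contig, genotype, run, run_class)
                    run, run_class = [frag], klass
            flush(contig, genotype, run, run_class)
    return pd.DataFrame(
        events,
        columns=["contig", "genotype", "class", "fragment_ids", "n_fragments", "start", "end"],
    )


@dataclass(frozen=True)
class Concordance:
    frac_a_in_b: float
    frac_b_in_a: float
    n_a: int
    n_b: int
    n_common: int


def cross_design_concordance(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> Concordance:
    """Fraction of A's calls recovered by B (fragment + genotype + class),
    with the symmetric fraction alongside."""
    key = ["fragment_id", "genotype", "class"]
    a = set(map(tuple, calls_a[key].itertuples(index=False)))
    b = set(map(tuple, calls_b[key].itertuples(index=False)))
    if not a:
        raise ValueError("call set A is empty: concordance undefined")
    common = len(a & b)
    return Concordance(
        frac_a_in_b=common / len(a),
        frac_b_in_a=common / len(b) if b else 0.0,
        n_a=len(a),
        n_b=len(b),
        n_common=common,
    )
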