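"""Reference experiments on synthetic data.

These routines recompute the package's headline quantities from scratch:
the stratified-split arithmetic on the published per-state corpus sizes,
cross-validated classification of a simulated corpus, agreement of the Burg
spectra with an FFT periodogram, AR-coefficient recovery, and the
directional replication of the fatigue band-power signature.  They are used
by the acceptance harness and are handy as worked examples.

The evaluation corpus is 300 epochs per state (60 s, 32 channels, 500 Hz,
default state profiles) run through the full preprocessing, spectral and
topographic stages; the network trains for 6 epochs per fold — enough for
convergence on this corpus while keeping a 10-fold run in the minutes
range on one CPU.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import periodogram

from . import classifier, pipeline, spectral, synthetic
from .preprocess import STATES

__all__ = [
    "published_split_counts",
    "split_arithmetic",
    "build_evaluation_corpus",
    "parameter_recovery",
    "directional_replication",
    "spectral_oracle",
]

#: Per-state corpus sizes of the reference drowsiness study (total 18,300).
PUBLISHED_TOTALS = {"normal": 8880, "critical": 5496, "fatigue": 3924}

EVAL_PER_STATE = 300
EVAL_FOLDS = 10
EVAL_EPOCHS = 6


def published_split_counts():
    return dict(PUBLISHED_TOTALS)


def split_arithmetic(seed: int = 0) -> dict:
    """Apply the stratified 75/25 split to the published per-state totals.

    Returns the realised per-state train/test counts plus the totals.
    """
    labels = np.concatenate([
        np.full(n, s) for s, n in PUBLISHED_TOTALS.items()
    ])
    tr, te = classifier.split_dataset(labels, train_fraction=0.75, seed=seed)
    out = {"train_total": int(tr.size), "test_total": int(te.size)}
    for s in STATES:
        out[f"train_{s}"] = int((labels[tr] == s).sum())
        out[f"test_{s}"] = int((labels[te] == s).sum())
    return out


def build_evaluation_corpus(seed: int, per_state: int = EVAL_PER_STATE):
    """Simulate and featurize the evaluation corpus; (X, y, features)."""
    config = pipeline.PipelineConfig(
        seed=seed,
        counts={s: per_state for s in STATES},
    )
    return pipeline.build_corpus(config)


def parameter_recovery(x, y, seed: int, folds: int = EVAL_FOLDS,
                       epochs: int = EVAL_EPOCHS) -> dict:
    """Stratified k-fold CV of the CNN on a featurized corpus.

    Returns mean/min fold accuracy, macro AUC and the per-fold values.
    """
    cfg = classifier.TrainConfig(epochs=epochs, seed=seed)
    reports = classifier.kfold_cv(x, y, k=folds, config=cfg)
    accs = [r.overall_accuracy for r in reports]
    aucs = [r.auc["macro"] for r in reports if r.auc]
    return {
        "mean_accuracy": float(np.mean(accs)),
        "min_accuracy": float(np.min(accs)),
        "macro_auc": float(np.mean(aucs)),
        "fold_accuracies": [float(a) for a in accs],
        "macro_precision": float(np.mean([r.macro.precision
                                          for r in reports])),
        "macro_sensitivity": float(np.mean([r.macro.sensitivity
                                            for r in reports])),
        "macro_f1": float(np.mean([r.macro.f1 for r in reports])),
        "n": int(np.asarray(y).size),
    }


def directional_replication(y, features) -> dict:
    """Fraction of fatigue/normal epoch pairs showing the fatigue signature.

    Pairs the i-th fatigue epoch with the i-th normal epoch and checks,
    on scalp-mean RPSD from the full spectral stage, that delta and theta
    are higher and alpha lower in the fatigue epoch.
    """
    y = np.asarray(y)
    mean_rpsd = {s: [f.rpsd.mean() for f, lab in zip(features, y)
                     if lab == s] for s in ("normal", "fatigue")}
    n_pairs = min(len(mean_rpsd["normal"]), len(mean_rpsd["fatigue"]))
    hits = {"delta": 0, "theta": 0, "alpha": 0}
    for i in range(n_pairs):
        fat = mean_rpsd["fatigue"][i]
        nor = mean_rpsd["normal"][i]
        hits["delta"] += bool(fat["delta"] > nor["delta"])
        hits["theta"] += bool(fat["theta"] > nor["theta"])
        hits["alpha"] += bool(fat["alpha"] < nor["alpha"])
    return {
        "fraction_delta_up": hits["delta"] / n_pairs,
        "fraction_theta_up": hits["theta"] / n_pairs,
        "fraction_alpha_down": hits["alpha"] / n_pairs,
        "fraction_all": min(hits.values()) / n_pairs,
        "n_pairs": int(n_pairs),
    }


def _simulate_ar(coeffs, n, seed, burn=500):
    from scipy.signal import lfilter

    rng = np.random.default_rng(seed)
    u = rng.standard_normal(n + burn)
    x = lfilter([1.0], np.r_[1.0, -np.asarray(coeffs, dtype=float)], u)
    return x[burn:]


def spectral_oracle(seed: int = 0, replicates: int = 50) -> dict:
    """Burg-vs-periodogram band-ratio agreement and AR(1) recovery.

    Over seeded AR(2) realizations, compares relative band powers from the
    AR(10) Burg spectrum against an FFT periodogram and reports the worst
    relative deviation; also fits AR(1) to a 0.9-coefficient process at
    n = 10,000 and reports the absolute coefficient error.  Realizations
    are 40,000 samples long so the periodogram's band sums average enough
    bins that the comparison measures estimator agreement rather than
    periodogram sampling noise (a raw periodogram bin has 100% relative
    variance at any length; the worst case over 50 x 4 band comparisons is
    a max statistic and needs a steady oracle).
    """
    fs = 200.0
    grid = spectral.default_grid(fs)
    total = ("total", 1.0, 30.0)
    worst = 0.0
    for r in range(replicates):
        x = _simulate_ar([0.6, -0.3], 40_000, seed=seed * 1000 + r)
        psd = spectral.burg_psd(spectral.fit_burg(x, 10), grid, fs)
        f, p = periodogram(x, fs=fs)
        tot = p[(f >= 1) & (f < 30)].sum()
        for name, lo, hi in spectral.DEFAULT_BANDS:
            lo, hi = max(lo, 1.0), min(hi, 30.0)
            oracle = p[(f >= lo) & (f < hi)].sum() / tot
            mine = spectral.rpsd(psd, grid, (name, lo, hi), total)
            worst = max(worst, abs(mine - oracle) / oracle)

    x1 = _simulate_ar([0.9], 10_000, seed=seed + 77)
    a1 = spectral.fit_burg(x1, p=1).coefficients[0]
    return {
        "worst_band_ratio_rel_err": float(worst),
        "ar1_abs_error": float(abs(-a1 - 0.9)),
        "replicates": replicates,
    }
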