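"""Group-level spectral statistics and the burden-of-pathology score.

Implements the machinery behind a classical qEEG contrast table: per
(channel, classical band) log10 band power compared between groups with
a pooled-variance two-sample t-test (df = n1 + n2 - 2) and Cohen's d.

Sign convention (matching the reference contrast table the simulator is
calibrated to): **d is positive when carrier power is higher** (d =
carrier - control over the pooled SD) while **t is oriented control -
carrier**, so t and d always carry opposite signs.

The full-spectrum group comparison is a label-permutation test on the
integrated squared distance between group-mean log spectra; the p-value
uses the add-one convention p = (1 + #{permuted >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import CLASSICAL_BANDS


def cohens_d(group1, group2) -> float:
    """Standardized mean difference (mean2 - mean1) / pooled SD."""
    x1, x2 = np.asarray(group1, float), np.asarray(group2, float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.sqrt(
        ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((x2.mean() - x1.mean()) / pooled)


def pooled_t(group1, group2) -> tuple[float, int, float]:
    """Classical pooled-variance two-sample t: (t, df, two-tailed p).

    t is oriented mean(group1) - mean(group2).
    """
    x1, x2 = np.asarray(group1, float), np.asarray(group2, float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / df
    if pooled_var == 0:
        raise ValueError("zero pooled variance")
    se = np.sqrt(pooled_var * (1 / n1 + 1 / n2))
    t = (x1.mean() - x2.mean()) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def t_from_d(d: float, n1: int, n2: int) -> float:
    """|t| implied by Cohen's d for a pooled two-sample test.

    The two statistics are linked by |t| = |d| * sqrt(n1*n2/(n1+n2)).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    return float(abs(d) * np.sqrt(n1 * n2 / (n1 + n2)))


def group_spectral_stats(band_powers: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Contrast-table statistics for every (channel, classical band) cell.

    ``band_powers`` is indexed by subject with MultiIndex columns
    (channel, band) of log10 band power; ``groups`` maps subject to
    'control'/'carrier'.  Returns one row per cell with group means, t
    (control - carrier), df, two-tailed p, and d (carrier - control).
    """
    groups = groups.loc[band_powers.index]
    ctrl = band_powers[groups == "control"]
    carr = band_powers[groups == "carrier"]
    rows = []
    for col in band_powers.columns:
        x_ctrl, x_carr = ctrl[col].to_numpy(), carr[col].to_numpy()
        t, df, p = pooled_t(x_ctrl, x_carr)
        rows.append(
            {
                "channel": col[0],
                "band": col[1],
                "mean_control": x_ctrl.mean(),
                "mean_carrier": x_carr.mean(),
                "t": t,
                "df": df,
                "p": p,
                "d": cohens_d(x_ctrl, x_carr),
            }
        )
    return pd.DataFrame(rows)


def full_spectrum_group_test(
    log_spectra: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test for a global group difference in mean log spectra.

    ``log_spectra`` has shape (subjects, channels, bins).  The statistic
    integrates the squared distance between group-mean log spectra over
    frequency and sums over channels.  Returns (observed statistic, p).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    spectra = np.asarray(log_spectra, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("exactly two groups required")
    if min((labels == c).sum() for c in classes) < 2:
        raise ValueError("each group needs n >= 2")

    def stat(lab: np.ndarray) -> float:
        m1 = spectra[lab == classes[0]].mean(axis=0)
        m2 = spectra[lab == classes[1]].mean(axis=0)
        return float(np.sum((m1 - m2) ** 2))

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if stat(perm) >= observed:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return observed, float(p)


@dataclass(frozen=True)
class BurdenScore:
    score: float
    included: bool  # study inclusion required score > 250


def burden_score(cag: float, age: float) -> BurdenScore:
    """CAG-age burden of pathology: (CAG - 35.5) x age, inclusion at > 250."""
    if cag <= 0 or age <= 0:
        raise ValueError("cag and age must be positive")
    score = (cag - 35.5) * age
    return BurdenScore(float(score), bool(score > 250))
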