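"""Group-level inference on subject-mean decoding accuracies."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from blockmvpa.errors import StatsError


def one_sample_t_onetailed(
    accuracies, chance: float = 50.0
) -> tuple[float, int, float]:
    """One-tailed one-sample t-test of subject accuracies above chance.

    Returns (t, df, upper-tail p).  Zero-variance samples at exactly the
    chance level return (0, df, 0.5) by contract; zero variance away from
    chance returns signed infinity with p 0 or 1.
    """
    a = np.asarray(accuracies, dtype=float)
    if a.ndim != 1 or len(a) < 2:
        raise StatsError(f"need >= 2 subjects, got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise StatsError("non-finite accuracy values")
    n = len(a)
    df = n - 1
    sd = a.std(ddof=1)
    diff = a.mean() - chance
    if sd == 0:
        if diff == 0:
            return 0.0, df, 0.5
        t = np.inf if diff > 0 else -np.inf
        return float(t), df, 0.0 if diff > 0 else 1.0
    t = diff / (sd / np.sqrt(n))
    p = float(scipy.stats.t.sf(t, df))
    return float(t), df, p


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Per-test threshold alpha/m, reported to 4 decimals."""
    if m < 1:
        raise StatsError(f"family size must be >= 1, got {m}")
    if not (0 < alpha <= 1):
        raise StatsError(f"alpha must be in (0, 1], got {alpha}")
    return round(alpha / m, 4)


def paired_t(accs_a, accs_b) -> tuple[float, int, float]:
    """Two-tailed paired t-test between two subject-aligned accuracy vectors."""
    a = np.asarray(accs_a, dtype=float)
    b = np.asarray(accs_b, dtype=float)
    if a.shape != b.shape:
        raise StatsError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 1 or len(a) < 2:
        raise StatsError("need >= 2 paired observations")
    d = a - b
    n = len(d)
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, df, 1.0
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * float(scipy.stats.t.sf(abs(t), df))
    return float(t), df, p


def rm_anova_2x2(
    table: np.ndarray,
    factor_names: tuple[str, str] = ("region", "hemisphere"),
) -> pd.DataFrame:
    """2x2 repeated-measures ANOVA from the raw sums-of-squares decomposition.

    ``table`` is (n_subjects, 2, 2): axis 1 is the first factor, axis 2
    the second.  Each effect is tested against its own subject-by-effect
    interaction error term on (1, n-1) df.  A zero error sum of squares
    with a nonzero effect is reported as F = inf, p = 0 with a warning.
    """
    y = np.asarray(table, dtype=float)
    if y.ndim != 3 or y.shape[1:] != (2, 2):
        raise StatsError(f"expected (n, 2, 2) table, got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise StatsError("missing cell (non-finite value) in the design")
    n = y.shape[0]
    if n < 2:
        raise StatsError("need >= 2 subjects")

    grand = y.mean()
    subj = y.mean(axis=(1, 2))  # per-subject means
    m_a = y.mean(axis=(0, 2))  # factor-A level means
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)  # subject x A
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)  # A x B cell means

    ss_a = 2 * n * ((m_a - grand) ** 2).sum()
    ss_b = 2 * n * ((m_b - grand) ** 2).sum()
    ss_ab = n * (
        (m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2
    ).sum()
    ss_err_a = 2 * (
        (m_sa - subj[:, None] - m_a[None, :] + grand) ** 2
    ).sum()
    ss_err_b = 2 * (
        (m_sb - subj[:, None] - m_b[None, :] + grand) ** 2
    ).sum()
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + subj[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_err_ab = (resid**2).sum()

    df_effect, df_err = 1, n - 1
    rows = []
    for name, ss_eff, ss_err in [
        (factor_names[0], ss_a, ss_err_a),
        (factor_names[1], ss_b, ss_err_b),
        (f"{factor_names[0]}:{factor_names[1]}", ss_ab, ss_err_ab),
    ]:
        ms_eff = ss_eff / df_effect
        ms_err = ss_err / df_err
        if ms_err == 0:
            if ms_eff == 0:
                f, p = 0.0, 1.0
            else:
                warnings.warn(
                    f"zero error variance for effect {name!r}; F reported as inf",
                    RuntimeWarning,
                    stacklevel=2,
                )
                f, p = np.inf, 0.0
        else:
            f = ms_eff / ms_err
            p = float(scipy.stats.f.sf(f, df_effect, df_err))
        rows.append(
            dict(effect=name, ss=ss_eff, ss_error=ss_err, df1=df_effect, df2=df_err, F=f, p=p)
        )
    return pd.DataFrame(rows)


def group_report(
    accuracies_by_roi: dict[str, np.ndarray],
    families: dict[str, str],
    family_alpha: float = 0.05,
    chance: float = 50.0,
) -> pd.DataFrame:
    """Per-ROI one-tailed test vs chance with family-wise Bonferroni flags.

    ``families`` maps ROI name -> family label; the per-test threshold in
    each family is alpha divided by that family's size.
    """
    missing = set(accuracies_by_roi) - set(families)
    if missing:
        raise StatsError(f"ROIs without family assignment: {sorted(missing)}")
    fam_sizes: dict[str, int] = {}
    for roi in accuracies_by_roi:
        fam = families[roi]
        fam_sizes[fam] = fam_sizes.get(fam, 0) + 1
    rows = []
    for roi, accs in accuracies_by_roi.items():
        accs = np.asarray(accs, dtype=float)
        t, df, p = one_sample_t_onetailed(accs, chance=chance)
        fam = families[roi]
        thresh = bonferroni_threshold(family_alpha, fam_sizes[fam])
        rows.append(
            dict(
                roi=roi,
                n_subjects=len(accs),
                mean_accuracy=float(accs.mean()),
                sem=float(accs.std(ddof=1) / np.sqrt(len(accs))),
                t=t,
                df=df,
                p_one_tailed=p,
                family=fam,
                family_size=fam_sizes[fam],
                threshold=thresh,
                significant=p < thresh,
            )
        )
    return pd.DataFrame(rows)


def format_group_summary(report: pd.DataFrame) -> str:
    """Human-readable text summary of a group report table."""
    lines = []
    for _, r in report.iterrows():
        flag = "*" if r["significant"] else " "
        lines.append(
            f"{flag} {r['roi']:<24s} {r['mean_accuracy']:5.1f}% "
            f"(SEM {r['sem']:.1f}) t({r['df']}) = {r['t']:.2f}, "
            f"p = {r['p_one_tailed']:.4f} [{r['family']}, "
            f"threshold {r['threshold']:.4f}]"
        )
    return "\n".join(lines)
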