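"""Two-library differential expression of miRNAs from read counts.

Expression is normalised to TPM per library; female/male fold changes and
log2 ratios are computed; per-miRNA counts are tested against the library
totals with Fisher's exact test (default decision) and the 1-df chi-square
test; p-values are Benjamini-Hochberg adjusted; miRNAs with a >= 2-fold
change and adjusted p < 0.05 are called differentially expressed. Also
provides the 2^-ddCt calculator used for qPCR validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class DifferentialResult:
    mirna_id: str
    sequence: str
    count_F: int
    count_M: int
    tpm_F: float
    tpm_M: float
    fold_change: float  # tpm_F / tpm_M; inf when tpm_M == 0
    log2_fc: float | None  # defined iff both TPM > 0
    p_raw: float
    p_adj: float = math.nan
    de_call: str = "ns"  # up_female | up_male | ns
    library_specific: bool = False


def tpm(count: int, library_total: int) -> float:
    """Tags per million: count / library_total * 1e6."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / library_total * 1e6


def fold_change(tpm_F: float, tpm_M: float) -> tuple[float, float | None, bool]:
    """(ratio, log2 ratio or None, library-specific flag).

    ratio = tpm_F / tpm_M computed on the unrounded TPMs; 0.0 when the
    female TPM is zero and inf when the male TPM is zero (both flagged
    library-specific, with log2 undefined).
    """
    if tpm_F < 0 or tpm_M < 0:
        raise ValueError("TPM values must be non-negative")
    if tpm_F == 0 and tpm_M == 0:
        raise ValueError("fold change undefined when both TPMs are zero")
    if tpm_M == 0:
        return math.inf, None, True
    ratio = tpm_F / tpm_M
    if tpm_F == 0:
        return 0.0, None, True
    return ratio, math.log2(ratio), False


def fisher_test(count_F: int, total_F: int, count_M: int, total_M: int) -> float:
    """Two-sided Fisher exact p for [[count_F, rest_F], [count_M, rest_M]].

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed one (with the
    conventional 1+1e-7 tie guard).
    """
    if min(count_F, count_M) < 0 or count_F > total_F or count_M > total_M:
        raise ValueError("counts must be non-negative and within totals")
    n = total_F + total_M
    r = count_F + count_M
    lo, hi = max(0, r - total_M), min(r, total_F)
    k = np.arange(lo, hi + 1)
    probs = stats.hypergeom.pmf(k, n, r, total_F)
    p_obs = probs[count_F - lo]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-7)].sum()))


def chisq_test(
    count_F: int, total_F: int, count_M: int, total_M: int, yates: bool = False
) -> float:
    """1-df chi-square p on the same 2x2 table (optional Yates correction)."""
    a, b = count_F, total_F - count_F
    c, d = count_M, total_M - count_M
    n = a + b + c + d
    for margin in (a + b, c + d, a + c, b + d):
        if margin == 0:
            raise ValueError("chi-square undefined with a zero margin")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2)
    chi2 = n * diff**2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return float(stats.chi2.sf(chi2, df=1))


def adjust_p(p_values, method: str = "bh") -> list[float]:
    """Benjamini-Hochberg (default) or Bonferroni adjustment, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return list(np.minimum(1.0, p * p.size))
    if method != "bh":
        raise ValueError(f"unknown adjustment method {method!r}")
    return list(stats.false_discovery_control(p, method="bh"))


def call_de(
    results: list[DifferentialResult],
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    p_adjust_method: str = "bh",
) -> list[DifferentialResult]:
    """Adjust p-values and set de_call on each result (in place, returned).

    up_female iff ratio >= fc_threshold, up_male iff ratio <= 1/fc_threshold,
    each additionally requiring adjusted p < alpha. Library-specific entries
    (one TPM zero) satisfy the fold condition trivially.
    """
    adj = adjust_p([r.p_raw for r in results], method=p_adjust_method)
    for r, pa in zip(results, adj):
        r.p_adj = float(pa)
        r.de_call = "ns"
        if pa < alpha:
            if r.fold_change >= fc_threshold:
                r.de_call = "up_female"
            elif r.fold_change <= 1.0 / fc_threshold:
                r.de_call = "up_male"
    return results


def differential_expression(
    counts: dict[str, tuple[int, int]],
    total_F: int,
    total_M: int,
    sequences: dict[str, str] | None = None,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    test: str = "fisher",
    p_adjust_method: str = "bh",
) -> list[DifferentialResult]:
    """Full two-library DE analysis from per-miRNA (count_F, count_M) pairs."""
    results = []
    for mid in sorted(counts):
        cf, cm = counts[mid]
        if cf == 0 and cm == 0:
            continue
        tf, tm = tpm(cf, total_F), tpm(cm, total_M)
        ratio, l2, spec = fold_change(tf, tm)
        if test == "fisher":
            p = fisher_test(cf, total_F, cm, total_M)
        elif test == "chisq":
            p = chisq_test(cf, total_F, cm, total_M)
        else:
            raise ValueError(f"unknown test {test!r}")
        results.append(
            DifferentialResult(
                mirna_id=mid,
                sequence=(sequences or {}).get(mid, ""),
                count_F=cf,
                count_M=cm,
                tpm_F=tf,
                tpm_M=tm,
                fold_change=ratio,
                log2_fc=l2,
                p_raw=p,
                library_specific=spec,
            )
        )
    return call_de(results, fc_threshold=fc_threshold, alpha=alpha,
                   p_adjust_method=p_adjust_method)


def ddct(
    ct_target_cond: float,
    ct_ref_cond: float,
    ct_target_base: float,
    ct_ref_base: float,
) -> float:
    """Relative expression by the 2^-ddCt method."""
    ddct_val = (ct_target_cond - ct_ref_cond) - (ct_target_base - ct_ref_base)
    return 2.0 ** (-ddct_val)


def round_ratio(ratio: float) -> str:
    """Report formatting for fold-change ratios: 3 decimal places; inf flagged."""
    if math.isinf(ratio):
        return "inf"
    return f"{ratio:.3f}"


def de_table(results: list[DifferentialResult], families: dict[str, str] | None = None) -> "pd.DataFrame":
    """Differential-expression report with fixed column order and rounding."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "miRNA-name": r.mirna_id,
                "Sequence": r.sequence.replace("T", "U"),
                "Length": len(r.sequence),
                "Family": (families or {}).get(r.mirna_id, ""),
                "TPM female": f"{r.tpm_F:.2f}",
                "TPM male": f"{r.tpm_M:.2f}",
                "Female/male": round_ratio(r.fold_change),
                "Log2 (fold change)": "" if r.log2_fc is None else f"{r.log2_fc:.4f}",
                "p_raw": f"{r.p_raw:.3g}",
                "p_adj": f"{r.p_adj:.3g}",
                "DE call": r.de_call,
                "Library specific": "yes" if r.library_specific else "",
            }
        )
    return pd.DataFrame(rows)
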