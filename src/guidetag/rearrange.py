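"""Translocation/large-deletion aggregation and the statistical toolkit.

Rates (indel frequency, translocation rate among edited UMIs) are variance-
stabilised with the arcsine-square-root transform before testing. Two-group
designs use Welch's t-test; multi-group designs use one-way ANOVA followed
by pre-specified pairwise contrasts on the pooled error term. P-values are
corrected per experiment with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .outcomes import Classification, EditClass, blunt_cut
from .seqio import GenomicInterval, revcomp


# ---------------------------------------------------------------------------
# Translocation events
# ---------------------------------------------------------------------------

@dataclass
class TranslocationEvent:
    """Aggregated junctions between the anchor cut site and one partner."""

    site_a: GenomicInterval
    site_b: GenomicInterval
    arm_a: str = "L"
    arm_b: str = "R"
    umi_counts: dict[str, int] = field(default_factory=dict)
    rates: dict[str, float] = field(default_factory=dict)
    p_value: float | None = None
    p_adjusted: float | None = None

    def total_umis(self) -> int:
        return sum(self.umi_counts.values())


def _arm_of(anchor_cut: int, seg_end: int) -> str:
    """Which chromosome arm (relative to the cut) a junction retains."""
    return "L" if seg_end <= anchor_cut else "R"


def call_translocations(
    candidates: Iterable[tuple[str, Classification]],
    known_sites: pd.DataFrame,
    anchor: GenomicInterval,
    anchor_cut: int,
    tolerance_bp: int = 25,
) -> tuple[list[TranslocationEvent], list[tuple[str, Classification]]]:
    """Aggregate translocation-candidate exemplars into per-partner events.

    ``candidates`` yields (sample, classification) pairs whose class is
    translocation_candidate. A candidate joins an event when its distal
    segment lies within ``tolerance_bp`` of a known site's protospacer
    interval; candidates matching no known site are returned separately as
    novel partners. Events are keyed by (partner site, arm combination).
    """
    events: dict[tuple, TranslocationEvent] = {}
    novel: list[tuple[str, Classification]] = []
    site_rows = list(known_sites.itertuples(index=False))
    for sample, cls in candidates:
        if cls.edit_class is not EditClass.translocation_candidate \
                or cls.partner is None:
            continue
        contig, pos, strand = cls.partner
        match = None
        for row in site_rows:
            if row.contig == contig and \
                    row.start - tolerance_bp <= pos <= row.end + tolerance_bp:
                match = row
                break
        if match is None:
            novel.append((sample, cls))
            continue
        seg1 = cls.split.segments[0] if cls.split else None
        arm_a = _arm_of(anchor_cut, seg1.ref_end) if seg1 else "L"
        site_cut = blunt_cut(match.start, match.end, match.strand)
        arm_b = "R" if pos >= site_cut else "L"
        key = (match.contig, match.start, match.end, arm_a, arm_b)
        ev = events.get(key)
        if ev is None:
            ev = TranslocationEvent(
                site_a=anchor,
                site_b=GenomicInterval(match.contig, match.start, match.end,
                                       match.strand),
                arm_a=arm_a, arm_b=arm_b)
            events[key] = ev
        ev.umi_counts[sample] = ev.umi_counts.get(sample, 0) + 1
    ordered = [events[k] for k in sorted(events)]
    return ordered, novel


def attach_rates(events: Sequence[TranslocationEvent],
                 edited_umis_per_sample: Mapping[str, int]) -> None:
    """Per-sample translocation rate among edited (non-wild-type) UMIs."""
    for ev in events:
        for sample, denom in edited_umis_per_sample.items():
            count = ev.umi_counts.get(sample, 0)
            ev.rates[sample] = count / denom if denom else 0.0


def predicted_junction(
    genome,
    cut_a: int, contig_a: str, arm_a: str,
    cut_b: int, contig_b: str, arm_b: str,
    flank: int = 20,
) -> str:
    """Reference sequence of a precise blunt ligation between two cut sites.

    The L arm of a site contributes the ``flank`` bases ending at its cut;
    the R arm the ``flank`` bases starting at it. Joining L(a) to R(b)
    reads straight through the junction; L+L and R+R joins invert the
    second arm. Joining a site's own two arms (which reconstitutes the
    unbroken reference) is rejected as an invalid combination.
    """
    if arm_a not in "LR" or arm_b not in "LR":
        raise ValueError("arms must be 'L' or 'R'")
    if contig_a == contig_b and cut_a == cut_b and {arm_a, arm_b} == {"L", "R"}:
        raise ValueError("joining a site's own arms reconstitutes the reference")
    seq_a = genome[contig_a]
    seq_b = genome[contig_b]
    left = seq_a[max(cut_a - flank, 0):cut_a] if arm_a == "L" \
        else revcomp(seq_a[cut_a:cut_a + flank])
    right = seq_b[cut_b:cut_b + flank] if arm_b == "R" \
        else revcomp(seq_b[max(cut_b - flank, 0):cut_b])
    return left + right


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass
class StatResult:
    """One hypothesis test on (transformed) rates."""

    test: str
    statistic: float | None
    p: float | None
    df: float | None = None
    raw_group1: tuple[float, ...] = ()
    raw_group2: tuple[float, ...] = ()
    transformed: bool = True
    untestable: bool = False
    reason: str = ""
    p_adjusted: float | None = None


def arcsine_transform(p):
    """Variance-stabilising arcsin(sqrt(p)) for proportions in [0, 1]."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def group_test(treated: Sequence[float], control: Sequence[float],
               transform: bool = True) -> StatResult:
    """Welch two-sample t-test on (arcsine-transformed) rates.

    Uses unequal-variance t with Welch-Satterthwaite degrees of freedom and
    a two-sided p. Groups where the test is undefined (n < 2 anywhere, or
    both groups with zero variance and equal means handled as t = 0, p = 1;
    both zero-variance with different means is untestable) are flagged
    rather than improvised.
    """
    t_raw = tuple(float(x) for x in treated)
    c_raw = tuple(float(x) for x in control)
    res = StatResult(test="welch_t", statistic=None, p=None,
                     raw_group1=t_raw, raw_group2=c_raw, transformed=transform)
    if len(t_raw) < 2 or len(c_raw) < 2:
        res.untestable = True
        res.reason = "need at least two observations per group"
        return res
    x = arcsine_transform(t_raw) if transform else np.asarray(t_raw)
    y = arcsine_transform(c_raw) if transform else np.asarray(c_raw)
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            res.statistic, res.p, res.df = 0.0, 1.0, float(len(x) + len(y) - 2)
            return res
        res.untestable = True
        res.reason = "zero variance in both groups with unequal means"
        return res
    t, p = sps.ttest_ind(x, y, equal_var=False)
    # Welch-Satterthwaite df, reported for transparency
    v1, v2 = np.var(x, ddof=1) / len(x), np.var(y, ddof=1) / len(y)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (len(x) - 1) + v2 ** 2 / (len(y) - 1)) \
        if (v1 + v2) > 0 else float(len(x) + len(y) - 2)
    res.statistic, res.p, res.df = float(t), float(p), float(df)
    return res


def anova_contrasts(groups: Mapping[str, Sequence[float]],
                    contrasts: Sequence[tuple[str, str]],
                    transform: bool = True) -> dict:
    """One-way ANOVA (completely randomised) with pre-specified contrasts.

    Each contrast (g1, g2) is tested with the pooled within-group mean
    square: t = (m1 - m2) / sqrt(MSE * (1/n1 + 1/n2)) on N - k df,
    two-sided.
    """
    names = list(groups)
    data = {g: (arcsine_transform(v) if transform else np.asarray(v, float))
            for g, v in groups.items()}
    if len(names) < 3:
        raise ValueError("ANOVA path requires more than two groups")
    f, p = sps.f_oneway(*(data[g] for g in names))
    N = sum(len(v) for v in data.values())
    k = len(names)
    mse = sum((len(v) - 1) * np.var(v, ddof=1) for v in data.values()) / (N - k)
    results = []
    for g1, g2 in contrasts:
        a, b = data[g1], data[g2]
        se = math.sqrt(mse * (1 / len(a) + 1 / len(b)))
        if se == 0:
            results.append(StatResult(test=f"contrast:{g1}-{g2}",
                                      statistic=None, p=None, untestable=True,
                                      reason="zero pooled variance"))
            continue
        t = (np.mean(a) - np.mean(b)) / se
        pc = 2 * sps.t.sf(abs(t), N - k)
        results.append(StatResult(test=f"contrast:{g1}-{g2}",
                                  statistic=float(t), p=float(pc),
                                  df=float(N - k)))
    return {"anova_F": float(f), "anova_p": float(p), "contrasts": results}


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def adjust_events(events: Sequence[TranslocationEvent],
                  results: Sequence[StatResult]) -> None:
    """Attach BH-adjusted p-values across an experiment's testable events."""
    testable = [(ev, r) for ev, r in zip(events, results)
                if not r.untestable and r.p is not None]
    if not testable:
        return
    adj = bh_adjust([r.p for _, r in testable])
    for (ev, r), a in zip(testable, adj):
        r.p_adjusted = float(a)
        ev.p_value = r.p
        ev.p_adjusted = float(a)


@dataclass
class CorrelationResult:
    r: float | None
    r_p: float | None
    rho: float | None
    rho_p: float | None
    n: int
    undefined: bool = False


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r (p from the t distribution on n-2 df) and Spearman rho."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        return CorrelationResult(None, None, None, None, len(x), undefined=True)
    r, rp = sps.pearsonr(x, y)
    rho, rhop = sps.spearmanr(x, y)
    return CorrelationResult(float(r), float(rp), float(rho), float(rhop),
                             len(x))


def deletion_spectrum(lengths: Sequence[int],
                      samples: Sequence[str] | None = None,
                      bins: Sequence[int] | None = None) -> dict:
    """Histogram of large-deletion lengths plus per-sample mean +/- SD."""
    lengths = np.asarray(lengths, dtype=int)
    if bins is None:
        bins = [50, 100, 200, 500, 1000, 2000, 5000]
    if lengths.size == 0:
        counts = np.zeros(len(bins) - 1, dtype=int)
        return {"bin_edges": np.asarray(bins), "counts": counts,
                "per_sample": pd.DataFrame(columns=["sample", "mean", "sd", "n"])}
    counts, edges = np.histogram(lengths, bins=bins)
    per_sample = pd.DataFrame(columns=["sample", "mean", "sd", "n"])
    if samples is not None:
        groups = defaultdict(list)
        for s, ln in zip(samples, lengths):
            groups[s].append(ln)
        per_sample = pd.DataFrame([
            {"sample": s, "mean": float(np.mean(v)),
             "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
             "n": len(v)}
            for s, v in sorted(groups.items())
        ])
    return {"bin_edges": edges, "counts": counts, "per_sample": per_sample}


def events_to_table(events: Sequence[TranslocationEvent]) -> pd.DataFrame:
    """Arc-table export: one row per event with counts, rates and p-values."""
    rows = []
    for ev in events:
        rows.append({
            "contig_a": ev.site_a.contig,
            "pos_a": ev.site_a.start,
            "arm_a": ev.arm_a,
            "contig_b": ev.site_b.contig,
            "pos_b": ev.site_b.start,
            "arm_b": ev.arm_b,
            "umi_count": ev.total_umis(),
            "mean_rate": float(np.mean(list(ev.rates.values()))) if ev.rates else 0.0,
            "p": ev.p_value,
            "p_adj": ev.p_adjusted,
        })
    return pd.DataFrame(rows, columns=["contig_a", "pos_a", "arm_a",
                                       "contig_b", "pos_b", "arm_b",
                                       "umi_count", "mean_rate", "p", "p_adj"])
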