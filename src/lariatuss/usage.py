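"""Per-splice-site usage (USS) from paired exonic/intronic coverage windows.

For a donor the windows are the last 40 nt of the upstream exon (count a)
and the first 40 nt of the intron (count b); for an acceptor the last 40 nt
of the intron and the first 40 nt of the downstream exon.  The default
usage statistic is the exonic coverage share, uss = a / (a + b): a fully
spliced intron leaves the intronic window empty, so uss -> 1.  The
differential screen pools counts per condition, applies the Fisher exact
test per site and BH correction across sites, and reports both the raw-p
and the FDR screen (FDR is the default flag).
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import ACCEPTOR, DONOR, GeneModel, SpliceSite, intron_sites
from .events import ASEvent, parse_junction_key
from .stats import bh_fdr, fisher_exact_2x2

USS_FORMULAS = ("exonic_share", "one_minus_ratio")


def compute_uss(a: float, b: float, formula: str = "exonic_share") -> float | None:
    """Usage statistic from exonic-window count a and intronic-window count b.

    ``exonic_share`` (default): a / (a + b).
    ``one_minus_ratio``: 1 - b / a, clipped to [0, 1] (undefined when a = 0).
    Returns None (undefined usage) when the formula's denominator is empty.
    """
    if a < 0 or b < 0:
        raise ValueError("negative window count")
    if formula == "exonic_share":
        if a + b == 0:
            return None
        return a / (a + b)
    if formula == "one_minus_ratio":
        if a == 0:
            return None
        return float(np.clip(1.0 - b / a, 0.0, 1.0))
    raise ValueError(f"unknown USS formula {formula!r}; choose from {USS_FORMULAS}")


def expected_counts_for_uss(uss: float, total: float, formula: str = "exonic_share") -> tuple[float, float]:
    """Invert the usage formula: expected (a, b) with a + b = total.

    Used by the synthetic generator so that simulated window counts have the
    requested true usage in expectation.
    """
    if not 0.0 <= uss <= 1.0:
        raise ValueError("uss outside [0, 1]")
    if formula == "exonic_share":
        return uss * total, (1.0 - uss) * total
    if formula == "one_minus_ratio":
        # a(1 - uss) = b with a + b = total
        a = total / (2.0 - uss)
        return a, total - a
    raise ValueError(f"unknown USS formula {formula!r}")


def site_windows(
    site: SpliceSite, models: Iterable[GeneModel], window: int = 40
) -> tuple[tuple[int, int], tuple[int, int], bool]:
    """Strand-aware (exonic_interval, intronic_interval, short_flag).

    Intervals are genomic 0-based half-open and abut at the boundary.  When
    the flanking exon or intron is shorter than ``window`` the interval is
    truncated to its length and the short flag set.  The flanking exon
    length is the maximum over transcripts containing the site and the
    intron length the minimum (the window never crosses the nearest
    annotated opposite boundary).
    """
    exon_len, intron_len = _flank_lengths(site, models)
    we, wi = min(window, exon_len), min(window, intron_len)
    short = we < window or wi < window
    b = site.boundary
    if site.kind == DONOR:
        if site.strand == "+":
            exonic, intronic = (b - we, b), (b, b + wi)
        else:
            exonic, intronic = (b + 1, b + 1 + we), (b + 1 - wi, b + 1)
    else:
        if site.strand == "+":
            exonic, intronic = (b + 1, b + 1 + we), (b + 1 - wi, b + 1)
        else:
            exonic, intronic = (b - we, b), (b, b + wi)
    return exonic, intronic, short


def _flank_lengths(site: SpliceSite, models: Iterable[GeneModel]) -> tuple[int, int]:
    exon_lens, intron_lens = [], []
    for gene in models:
        if gene.chrom != site.chrom or gene.strand != site.strand:
            continue
        for tx in gene.transcripts:
            exons = gene.transcripts[tx]
            for i, intron in enumerate(gene.introns(tx)):
                d, a = intron_sites(gene.chrom, gene.strand, intron)
                if site == d:
                    up = exons[i] if gene.strand == "+" else exons[i + 1]
                    exon_lens.append(up[1] - up[0])
                    intron_lens.append(intron[1] - intron[0])
                elif site == a:
                    dn = exons[i + 1] if gene.strand == "+" else exons[i]
                    exon_lens.append(dn[1] - dn[0])
                    intron_lens.append(intron[1] - intron[0])
    if not exon_lens:
        raise LookupError(f"splice site {site.site_id} not found in the gene models")
    return max(exon_lens), min(intron_lens)


def differential_uss(
    window_counts: pd.DataFrame,
    control: str = "control",
    mutant: str = "mutant",
    delta_threshold: float = 0.01,
    fdr_threshold: float = 0.05,
    p_threshold: float = 0.05,
    formula: str = "exonic_share",
) -> pd.DataFrame:
    """Screen splice sites for differential usage between two conditions.

    ``window_counts`` columns: site_id, sample, condition, exonic_count,
    intronic_count (an optional boolean ``short_window`` column is carried
    through).  Counts are pooled per condition; delta_uss = uss(mutant) -
    uss(control).  Two flags are reported: ``significant`` (|dUSS| >
    threshold and FDR < fdr_threshold, the default screen) and
    ``significant_raw_p`` (|dUSS| > threshold and p < p_threshold).
    """
    df = window_counts.copy()
    missing = set(df["condition"]) - {control, mutant}
    if missing:
        raise ValueError(f"unknown condition labels: {sorted(missing)}")
    pooled = (
        df.groupby(["site_id", "condition"])[["exonic_count", "intronic_count"]].sum().unstack("condition")
    )
    pooled = pooled.fillna(0).astype(int)
    aa = pooled.get(("exonic_count", control), pd.Series(0, index=pooled.index))
    ba = pooled.get(("intronic_count", control), pd.Series(0, index=pooled.index))
    ab = pooled.get(("exonic_count", mutant), pd.Series(0, index=pooled.index))
    bb = pooled.get(("intronic_count", mutant), pd.Series(0, index=pooled.index))
    res = pd.DataFrame(
        {
            "site_id": pooled.index,
            "exonic_control": aa.values,
            "intronic_control": ba.values,
            "exonic_mutant": ab.values,
            "intronic_mutant": bb.values,
        }
    )
    uss_a = [compute_uss(a, b, formula) for a, b in zip(res["exonic_control"], res["intronic_control"])]
    uss_b = [compute_uss(a, b, formula) for a, b in zip(res["exonic_mutant"], res["intronic_mutant"])]
    res["uss_control"] = [np.nan if u is None else u for u in uss_a]
    res["uss_mutant"] = [np.nan if u is None else u for u in uss_b]
    res["testable"] = ~(res["uss_control"].isna() | res["uss_mutant"].isna())
    res["delta_uss"] = res["uss_mutant"] - res["uss_control"]
    res["p_value"] = np.nan
    t = res["testable"].values
    if t.any():
        p, _ = fisher_exact_2x2(
            res.loc[t, "exonic_control"],
            res.loc[t, "intronic_control"],
            res.loc[t, "exonic_mutant"],
            res.loc[t, "intronic_mutant"],
        )
        res.loc[t, "p_value"] = p
    res["fdr"] = bh_fdr(res["p_value"])
    big = res["delta_uss"].abs() > delta_threshold
    res["significant"] = res["testable"] & big & (res["fdr"] < fdr_threshold)
    res["significant_raw_p"] = res["testable"] & big & (res["p_value"] < p_threshold)
    if "short_window" in df.columns:
        flags = df.groupby("site_id")["short_window"].any()
        res["short_window"] = flags.reindex(res["site_id"]).fillna(False).values
    return res.sort_values("site_id").reset_index(drop=True)


def event_site_ids(event: ASEvent, kind: str) -> set[str]:
    """Splice sites of one kind (donor/acceptor) defining an event, read off
    its inclusion and skipping junction keys."""
    sites: set[str] = set()
    for key in event.inclusion_junctions | event.skipping_junctions:
        chrom, d, a, strand, _ = parse_junction_key(key)
        if kind == DONOR:
            sites.add(SpliceSite(chrom, strand, d, DONOR).site_id)
        else:
            sites.add(SpliceSite(chrom, strand, a, ACCEPTOR).site_id)
    return sites


def uss_event_enrichment(
    uss_table: pd.DataFrame,
    events: Sequence[ASEvent],
    psi_table: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Are usage-changed sites enriched among sites of significant DS events?

    For each event type and site kind, the tested sites are cross-tabulated
    by (usage-changed yes/no) x (participates in a significant differentially
    spliced event of that type yes/no); the association is assessed with a
    Fisher exact test and the odds ratio, BH-corrected across the strata.
    Empty strata yield NaN odds ratios.
    """
    universe = list(uss_table["site_id"])
    changed = set(uss_table.loc[uss_table["significant"], "site_id"])
    sig_events = set(psi_table.loc[psi_table["significant"], "event_id"])
    rows = []
    for etype in ("SE", "RI", "A5SS", "A3SS", "MXE"):
        for kind in (DONOR, ACCEPTOR):
            in_event: set[str] = set()
            for ev in events:
                if ev.type == etype and ev.event_id in sig_events:
                    in_event |= event_site_ids(ev, kind)
            n11 = n10 = n01 = n00 = 0
            for sid in universe:
                ch = sid in changed
                ine = sid in in_event
                if ch and ine:
                    n11 += 1
                elif ch:
                    n10 += 1
                elif ine:
                    n01 += 1
                else:
                    n00 += 1
            p, oddsr = fisher_exact_2x2(n11, n10, n01, n00)
            rows.append((etype, kind, n11, n10, n01, n00, float(oddsr[0]), float(p[0])))
    res = pd.DataFrame(
        rows, columns=["event_type", "site_kind", "n11", "n10", "n01", "n00", "odds_ratio", "p_value"]
    )
    testable = (res["n11"] + res["n01"] > 0) & (res["n10"] + res["n00"] > 0)
    res["p_value"] = res["p_value"].where(testable, np.nan)
    res["fdr"] = bh_fdr(res["p_value"])
    res["significant"] = (res["fdr"] < fdr_threshold) & (res["odds_ratio"] > 1)
    return res
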