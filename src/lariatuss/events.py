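"""Five-type alternative-splicing events: extraction, PSI, differential screen.

Event types follow the usual rMATS taxonomy: SE (skipped exon), RI (retained
intron), A5SS/A3SS (alternative donor/acceptor) and MXE (mutually exclusive
exons).  Events are discovered by pairwise comparison of a gene's isoforms
through their intron sets; PSI is the junction-support share of the
inclusion form, I/(I+S); the differential screen pools counts within each
condition, applies a two-sided Fisher exact test per event and
Benjamini-Hochberg correction across events, and flags events passing
|dPSI| > 0.05, FDR < 0.05 and supporting reads >= 5 (all configurable).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .stats import bh_fdr, fisher_exact_2x2

SE, RI, A5SS, A3SS, MXE = "SE", "RI", "A5SS", "A3SS", "MXE"
EVENT_TYPES = (SE, RI, A5SS, A3SS, MXE)


def junction_key(chrom: str, intron: tuple[int, int], strand: str, retention: bool = False) -> str:
    """Key of a spliced junction (or, with ``retention``, of the exon-intron
    boundary-spanning evidence for a retained intron).

    The key encodes the intron's donor and acceptor boundaries (first and
    last intronic base, internal 0-based coordinates): ``chrom:d-a:strand``;
    retention evidence uses ``^`` instead of ``-``.
    """
    s, e = intron
    d, a = (s, e - 1) if strand == "+" else (e - 1, s)
    sep = "^" if retention else "-"
    return f"{chrom}:{d}{sep}{a}:{strand}"


def parse_junction_key(key: str) -> tuple[str, int, int, str, bool]:
    """-> (chrom, donor_boundary, acceptor_boundary, strand, is_retention)."""
    chrom, mid, strand = key.rsplit(":", 2)
    retention = "^" in mid
    d, a = mid.split("^" if retention else "-")
    return chrom, int(d), int(a), strand, retention


@dataclass(frozen=True)
class ASEvent:
    """One alternative-splicing event with its defining coordinates.

    ``coords`` is type-specific (all internal genomic coordinates):
      SE   (x, c, d, y): upstream flank end, cassette exon [c, d), downstream flank start
      RI   (s, e): the retained intron [s, e)
      A5SS / A3SS (alt1, alt2, shared): the two alternative intron edges
           (sorted) and the shared opposite edge; ``alt_side`` says whether
           the alternative edges are the genomic left ("L") or right ("R")
           ends of the intron
      MXE  (x, c1, d1, c2, d2, y): flanks and the two exclusive exons in
           transcription order (exon 1 upstream on the transcribed strand)
    """

    type: str
    gene_id: str
    chrom: str
    strand: str
    coords: tuple[int, ...]
    inclusion_junctions: frozenset[str]
    skipping_junctions: frozenset[str]
    alt_side: str = ""

    @property
    def event_id(self) -> str:
        return f"{self.type}@{self.chrom}:{self.strand}:" + "|".join(map(str, self.coords))

    def distance(self) -> int | None:
        """Inter-site distance: intron length (RI) or alternative-site spacing
        (A5SS/A3SS); None for SE/MXE."""
        if self.type == RI:
            return self.coords[1] - self.coords[0]
        if self.type in (A5SS, A3SS):
            return abs(self.coords[1] - self.coords[0])
        return None


def _se_events(gene: GeneModel, i1: set, i2: set, t1_exons: list, t2_exons: list) -> list[ASEvent]:
    out = []
    ex2 = set(t2_exons)
    for idx, exon in enumerate(t1_exons[1:-1], start=1):
        if exon in ex2:
            continue
        x = t1_exons[idx - 1][1]
        y = t1_exons[idx + 1][0]
        c, d = exon
        if (x, c) in i1 and (d, y) in i1 and (x, y) in i2:
            incl = frozenset(
                {junction_key(gene.chrom, (x, c), gene.strand), junction_key(gene.chrom, (d, y), gene.strand)}
            )
            skip = frozenset({junction_key(gene.chrom, (x, y), gene.strand)})
            out.append(ASEvent(SE, gene.gene_id, gene.chrom, gene.strand, (x, c, d, y), incl, skip))
    return out


def _ri_events(gene: GeneModel, t1_exons: list, i1: set, t2_exons: list, i2: set) -> list[ASEvent]:
    # T2 retains an intron of T1: T1 has exons (a, s), (e, b); T2 has exon (a, b).
    out = []
    ex2 = set(t2_exons)
    for (a, s), (e, b) in zip(t1_exons, t1_exons[1:]):
        if (s, e) in i2 or (a, b) not in ex2:
            continue
        incl = frozenset({junction_key(gene.chrom, (s, e), gene.strand, retention=True)})
        skip = frozenset({junction_key(gene.chrom, (s, e), gene.strand)})
        out.append(ASEvent(RI, gene.gene_id, gene.chrom, gene.strand, (s, e), incl, skip))
    return out


def _alt_edge_events(gene: GeneModel, t1_exons, i1: set, t2_exons, i2: set) -> list[ASEvent]:
    """A5SS/A3SS: intron pairs sharing one edge, whose variable-edge exons
    share their distal boundary (so the shorter intron extends the exon)."""
    out = []
    ex_before_1 = {intr: exon for exon, intr in zip(t1_exons, _intron_list(t1_exons))}
    ex_after_1 = {intr: exon for intr, exon in zip(_intron_list(t1_exons), t1_exons[1:])}
    ex_before_2 = {intr: exon for exon, intr in zip(t2_exons, _intron_list(t2_exons))}
    ex_after_2 = {intr: exon for intr, exon in zip(_intron_list(t2_exons), t2_exons[1:])}
    for j1 in i1 - i2:
        for j2 in i2 - i1:
            if j1[1] == j2[1] and j1[0] != j2[0]:
                # alternative left edges; require shared upstream-exon start
                if ex_before_1[j1][0] != ex_before_2[j2][0]:
                    continue
                alt1, alt2 = sorted((j1[0], j2[0]))
                shared = j1[1]
                etype = A5SS if gene.strand == "+" else A3SS
                side = "L"
                short_intron = (alt2, shared)  # extended-exon (inclusion) form
                long_intron = (alt1, shared)
            elif j1[0] == j2[0] and j1[1] != j2[1]:
                if ex_after_1[j1][1] != ex_after_2[j2][1]:
                    continue
                alt1, alt2 = sorted((j1[1], j2[1]))
                shared = j1[0]
                etype = A3SS if gene.strand == "+" else A5SS
                side = "R"
                short_intron = (shared, alt1)
                long_intron = (shared, alt2)
            else:
                continue
            incl = frozenset({junction_key(gene.chrom, short_intron, gene.strand)})
            skip = frozenset({junction_key(gene.chrom, long_intron, gene.strand)})
            out.append(
                ASEvent(etype, gene.gene_id, gene.chrom, gene.strand, (alt1, alt2, shared), incl, skip, side)
            )
    return out


def _mxe_events(gene: GeneModel, t1_exons, i1: set, t2_exons, i2: set) -> list[ASEvent]:
    out = []
    ex2 = set(t2_exons)
    for idx, exon1 in enumerate(t1_exons[1:-1], start=1):
        if exon1 in ex2:
            continue
        x = t1_exons[idx - 1][1]
        y = t1_exons[idx + 1][0]
        c1, d1 = exon1
        if (x, c1) not in i1 or (d1, y) not in i1:
            continue
        for jdx, exon2 in enumerate(t2_exons[1:-1], start=1):
            if exon2 in set(t1_exons) or exon2 == exon1:
                continue
            c2, d2 = exon2
            if d2 <= c1 or d1 <= c2:  # non-overlapping exclusive exons
                if (x, c2) in i2 and (d2, y) in i2:
                    # transcription order: upstream = smaller coords on +, larger on -
                    if (gene.strand == "+") == (c1 < c2):
                        up, dn = (c1, d1), (c2, d2)
                    else:
                        up, dn = (c2, d2), (c1, d1)
                    incl = frozenset(
                        {
                            junction_key(gene.chrom, (x, up[0]), gene.strand),
                            junction_key(gene.chrom, (up[1], y), gene.strand),
                        }
                    )
                    skip = frozenset(
                        {
                            junction_key(gene.chrom, (x, dn[0]), gene.strand),
                            junction_key(gene.chrom, (dn[1], y), gene.strand),
                        }
                    )
                    out.append(
                        ASEvent(
                            MXE,
                            gene.gene_id,
                            gene.chrom,
                            gene.strand,
                            (x, up[0], up[1], dn[0], dn[1], y),
                            incl,
                            skip,
                        )
                    )
    return out


def _intron_list(exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    return [(e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:])]


def extract_events(models: Iterable[GeneModel]) -> list[ASEvent]:
    """Pairwise isoform comparison within each gene; deduplicated by
    (type, chrom, strand, defining coordinates)."""
    found: dict[tuple, ASEvent] = {}
    for gene in models:
        tx_ids = sorted(gene.transcripts)
        for i, ta in enumerate(tx_ids):
            for tb in tx_ids[i + 1 :]:
                ea, eb = gene.transcripts[ta], gene.transcripts[tb]
                ia, ib = set(_intron_list(ea)), set(_intron_list(eb))
                evs: list[ASEvent] = []
                evs += _se_events(gene, ia, ib, ea, eb) + _se_events(gene, ib, ia, eb, ea)
                evs += _ri_events(gene, ea, ia, eb, ib) + _ri_events(gene, eb, ib, ea, ia)
                evs += _alt_edge_events(gene, ea, ia, eb, ib)
                evs += _mxe_events(gene, ea, ia, eb, ib)
                for ev in evs:
                    found.setdefault((ev.type, ev.chrom, ev.strand, ev.coords), ev)
    return sorted(found.values(), key=lambda e: (e.chrom, e.coords, e.type))


def compute_psi(event: ASEvent, counts: Mapping[str, float]) -> tuple[float | None, int]:
    """PSI = I / (I + S) from junction-count sums over the event's junction
    sets; returns (psi or None when I + S == 0, supporting reads I + S).

    Keys absent from ``counts`` contribute zero (count tables may cover a
    superset or subset of the event's junctions).
    """
    inc = sum(counts.get(k, 0) for k in event.inclusion_junctions)
    skp = sum(counts.get(k, 0) for k in event.skipping_junctions)
    total = inc + skp
    if total == 0:
        return None, 0
    return inc / total, int(total)


def event_counts_from_junctions(
    events: Sequence[ASEvent], junction_df: pd.DataFrame
) -> pd.DataFrame:
    """Collapse a long junction-count table (junction, sample, condition,
    count) to per-event inclusion/skipping counts per sample."""
    out = []
    for (sample, condition), grp in junction_df.groupby(["sample", "condition"], sort=True):
        counts = dict(zip(grp["junction"], grp["count"]))
        for ev in events:
            inc = sum(counts.get(k, 0) for k in ev.inclusion_junctions)
            skp = sum(counts.get(k, 0) for k in ev.skipping_junctions)
            out.append((ev.event_id, sample, condition, int(inc), int(skp)))
    return pd.DataFrame(out, columns=["event_id", "sample", "condition", "inclusion", "skipping"])


def differential_psi(
    event_counts: pd.DataFrame,
    events: Sequence[ASEvent] | None = None,
    control: str = "control",
    mutant: str = "mutant",
    delta_threshold: float = 0.05,
    fdr_threshold: float = 0.05,
    min_reads: int = 5,
) -> pd.DataFrame:
    """Screen events for differential splicing between two conditions.

    ``event_counts`` columns: event_id, sample, condition, inclusion,
    skipping.  Counts are pooled within each condition; delta_psi =
    psi(mutant) - psi(control).  ``supporting_reads`` is the minimum of
    inclusion + skipping over individual samples.  Events with zero pooled
    counts in either condition are reported untestable (p, fdr = NaN) and
    excluded from the BH family.
    """
    df = event_counts.copy()
    missing = set(df["condition"]) - {control, mutant}
    if missing:
        raise ValueError(f"unknown condition labels: {sorted(missing)}")
    df["total"] = df["inclusion"] + df["skipping"]
    pooled = df.groupby(["event_id", "condition"])[["inclusion", "skipping"]].sum().unstack("condition")
    pooled = pooled.fillna(0).astype(int)
    ia = pooled.get(("inclusion", control), pd.Series(0, index=pooled.index))
    sa = pooled.get(("skipping", control), pd.Series(0, index=pooled.index))
    ib = pooled.get(("inclusion", mutant), pd.Series(0, index=pooled.index))
    sb = pooled.get(("skipping", mutant), pd.Series(0, index=pooled.index))
    support = df.groupby("event_id")["total"].min()

    res = pd.DataFrame(
        {
            "event_id": pooled.index,
            "inclusion_control": ia.values,
            "skipping_control": sa.values,
            "inclusion_mutant": ib.values,
            "skipping_mutant": sb.values,
            "supporting_reads": support.reindex(pooled.index).values,
        }
    )
    tot_a = res["inclusion_control"] + res["skipping_control"]
    tot_b = res["inclusion_mutant"] + res["skipping_mutant"]
    res["testable"] = (tot_a > 0) & (tot_b > 0)
    with np.errstate(invalid="ignore"):
        res["psi_control"] = np.where(tot_a > 0, res["inclusion_control"] / tot_a, np.nan)
        res["psi_mutant"] = np.where(tot_b > 0, res["inclusion_mutant"] / tot_b, np.nan)
    res["delta_psi"] = res["psi_mutant"] - res["psi_control"]

    res["p_value"] = np.nan
    t = res["testable"].values
    if t.any():
        p, _ = fisher_exact_2x2(
            res.loc[t, "inclusion_control"],
            res.loc[t, "skipping_control"],
            res.loc[t, "inclusion_mutant"],
            res.loc[t, "skipping_mutant"],
        )
        res.loc[t, "p_value"] = p
    res["fdr"] = bh_fdr(res["p_value"])
    res["significant"] = (
        res["testable"]
        & (res["delta_psi"].abs() > delta_threshold)
        & (res["fdr"] < fdr_threshold)
        & (res["supporting_reads"] >= min_reads)
    )
    if events is not None:
        meta = pd.DataFrame(
            {
                "event_id": [e.event_id for e in events],
                "type": [e.type for e in events],
                "gene_id": [e.gene_id for e in events],
                "distance": [e.distance() for e in events],
            }
        )
        res = res.merge(meta, on="event_id", how="left")
    return res.sort_values("event_id").reset_index(drop=True)


def distance_distribution(
    psi_table: pd.DataFrame,
    events: Sequence[ASEvent],
    direction: str = "increased",
    delta_threshold: float = 0.05,
    bin_width: int = 30,
    bin_start: int = 20,
    significant_only: bool = True,
) -> tuple[pd.DataFrame, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Inter-splice-site distances of screened RI/A5SS/A3SS events.

    RI uses the retained-intron length, A5SS the spacing of the two donors,
    A3SS the spacing of the two acceptors (SE/MXE have no single defining
    distance and are excluded).  ``direction`` selects events with
    delta_psi > +threshold ("increased") or < -threshold ("decreased").
    Returns (long table of distances, per-type histogram (edges, counts)).
    """
    if direction not in ("increased", "decreased"):
        raise ValueError("direction must be 'increased' or 'decreased'")
    by_id = {e.event_id: e for e in events}
    sel = psi_table
    if significant_only and "significant" in sel.columns:
        sel = sel[sel["significant"]]
    if direction == "increased":
        sel = sel[sel["delta_psi"] > delta_threshold]
    else:
        sel = sel[sel["delta_psi"] < -delta_threshold]
    rows = []
    for eid in sel["event_id"]:
        ev = by_id.get(eid)
        if ev is None or ev.type not in (RI, A5SS, A3SS):
            continue
        rows.append((eid, ev.type, ev.distance()))
    dist_df = pd.DataFrame(rows, columns=["event_id", "type", "distance"])
    hists: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for etype in (RI, A5SS, A3SS):
        d = dist_df.loc[dist_df["type"] == etype, "distance"].to_numpy()
        if d.size == 0:
            hists[etype] = (np.array([]), np.array([]))
            continue
        top = max(int(d.max()) + 1, bin_start + bin_width)
        edges = np.arange(bin_start, top + bin_width, bin_width)
        if d.min() < bin_start:
            edges = np.concatenate([[min(0, int(d.min()))], edges])
        counts, edges = np.histogram(d, bins=edges)
        hists[etype] = (edges, counts)
    return dist_df, hists


def modal_bin(hist: tuple[np.ndarray, np.ndarray]) -> tuple[int, int] | None:
    """(low, high) edges of the most populated histogram bin, or None."""
    edges, counts = hist
    if len(counts) == 0:
        return None
    i = int(np.argmax(counts))
    return int(edges[i]), int(edges[i + 1])
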