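"""Synthetic genomes, count tables and lariat reads with known ground truth.

Every downstream stage of the pipeline is exercised against data from this
module: toy genomes in which each gene carries exactly one designed
alternative-splicing event of a known type, junction/window count tables
drawn so that true PSI and USS are recovered in expectation, and
lariat-derived reads whose branch points are known per read.

The generated structures emulate the study design the statistics were
built for: two conditions (a control strain and an sf3b1-like mutant),
binomial junction sampling at Poisson depth, retained introns whose
up-regulated class sits in the 50-80 nt length band where short fly introns
concentrate, coverage-window counts consistent with a planted usage shift
at the affected sites, and Sanger-scale clone counts (10-12 per strain)
with a branch-adenosine-to-T misread rate of 0.7 and uniform sequencing
error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import events as ev
from .annotation import DONOR, GeneModel, enumerate_splice_sites, intron_sites, revcomp
from .lariat import IntronRef
from .usage import event_site_ids, expected_counts_for_uss

BASES = np.array(list("ACGT"))

DEFAULT_EVENT_MIX = {"SE": 0.2, "RI": 0.2, "A5SS": 0.2, "A3SS": 0.2, "MXE": 0.2}


class ConfigError(ValueError):
    pass


@dataclass
class SyntheticTruth:
    """Generator-side ground truth against which recovery is tested."""

    seed: int
    events: list[ev.ASEvent]
    events_df: pd.DataFrame  # event_id, gene_id, type, distance, psi_control, psi_mutant
    sites_df: pd.DataFrame  # site_id, kind, uss_control, uss_mutant, changed
    bp: dict[str, dict[int, float]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        for col in ("psi_control", "psi_mutant"):
            v = self.events_df[col]
            if ((v < 0) | (v > 1)).any():
                raise ConfigError(f"{col} outside [0, 1]")
        for col in ("uss_control", "uss_mutant"):
            v = self.sites_df[col]
            if ((v < 0) | (v > 1)).any():
                raise ConfigError(f"{col} outside [0, 1]")
        for intron_id, freqs in self.bp.items():
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"BP frequencies for {intron_id} do not sum to 1")

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "params": self.params,
            "events": self.events_df.to_dict(orient="records"),
            "sites": self.sites_df.to_dict(orient="records"),
            "bp": {k: {str(o): f for o, f in v.items()} for k, v in self.bp.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class LariatReadSet:
    """Simulated subclone reads from one (intron, strain) pair."""

    intron_id: str
    strain: str
    reads: list[tuple[str, str]]  # (read_id, sequence)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.reads:
                fh.write(f">{rid}\n{seq}\n")


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def _intron_seg(rng: np.random.Generator, n: int) -> str:
    """Random intron segment with canonical GT...AG ends (n >= 4)."""
    return "GT" + _rand_seq(rng, n - 4) + "AG"


def _map_intervals(local: list[tuple[int, int]], offset: int, gene_len: int, strand: str):
    if strand == "+":
        out = [(offset + s, offset + e) for s, e in local]
    else:
        out = [(offset + gene_len - e, offset + gene_len - s) for s, e in local]
    return sorted(out)


def _build_gene(rng: np.random.Generator, etype: str, delta_sign: int, cfg: dict):
    """One gene in transcription space.

    Returns (sequence, isoform_a_local, isoform_b_local, tags) where isoform
    A is the event's inclusion form (extended/retained/cassette-in/upstream-
    exclusive) and tags name the special segments for truth bookkeeping.
    """
    ex = lambda: int(rng.integers(*cfg["exon_len_range"]))
    intron = lambda: int(rng.integers(*cfg["intron_len_range"]))
    segs: list[tuple[str, int]] = []  # (label, length)
    if etype == "RI":
        ilen = (
            int(rng.integers(*cfg["ri_up_intron_len_range"]))
            if delta_sign > 0
            else intron()
        )
        segs = [("E1", ex()), ("I1", ilen), ("E2", ex())]
        a_exons = [("E1", "I1", "E2")]  # retained: one exon spanning all
        b_exons = [("E1",), ("E2",)]
    elif etype == "SE":
        segs = [("E1", ex()), ("I1", intron()), ("E2", ex()), ("I2", intron()), ("E3", ex())]
        a_exons = [("E1",), ("E2",), ("E3",)]
        b_exons = [("E1",), ("E3",)]
    elif etype == "A5SS":
        segs = [("E1", ex()), ("X", int(rng.integers(*cfg["a5ss_offset_range"]))), ("I1", intron()), ("E2", ex())]
        a_exons = [("E1", "X"), ("E2",)]
        b_exons = [("E1",), ("E2",)]
    elif etype == "A3SS":
        segs = [("E1", ex()), ("I1", intron()), ("Y", int(rng.integers(*cfg["a3ss_offset_range"]))), ("E2", ex())]
        a_exons = [("E1",), ("Y", "E2")]
        b_exons = [("E1",), ("E2",)]
    elif etype == "MXE":
        segs = [
            ("E1", ex()),
            ("I1", intron()),
            ("Ea", ex()),
            ("I2", intron()),
            ("Eb", ex()),
            ("I3", intron()),
            ("E2", ex()),
        ]
        a_exons = [("E1",), ("Ea",), ("E2",)]
        b_exons = [("E1",), ("Eb",), ("E2",)]
    else:
        raise ConfigError(f"unknown event type {etype!r}")

    pos = 0
    coords: dict[str, tuple[int, int]] = {}
    seq_parts: list[str] = []
    for label, n in segs:
        intronic = label.startswith("I") or label in ("X", "Y")
        # X/Y are exonic in the extended isoform but intron starts in the
        # short one; giving them GT starts keeps all composite introns
        # canonical.  Y must end with AG for the short intron, and segments
        # preceding Y or I segments need no constraint.
        if label.startswith("I"):
            seq_parts.append(_intron_seg(rng, n))
        elif label == "X":
            seq_parts.append("GT" + _rand_seq(rng, n - 2))
        elif label == "Y":
            seq_parts.append(_rand_seq(rng, n - 2) + "AG")
        else:
            seq_parts.append(_rand_seq(rng, n))
        coords[label] = (pos, pos + n)
        pos += n
        del intronic
    seq = "".join(seq_parts)

    def merge(labels: tuple[str, ...]) -> tuple[int, int]:
        return coords[labels[0]][0], coords[labels[-1]][1]

    iso_a = [merge(t) for t in a_exons]
    iso_b = [merge(t) for t in b_exons]
    return seq, iso_a, iso_b, coords


def _designed_event(gene: GeneModel, etype: str) -> ev.ASEvent:
    """Defining coordinates and junction sets of the one designed event,
    read off the constructed isoform pair (bookkeeping, not pattern
    discovery: which isoform is which is known by construction)."""
    iso_a = gene.transcripts["tA"]  # inclusion form
    iso_b = gene.transcripts["tB"]
    chrom, strand = gene.chrom, gene.strand
    jk = lambda intron, ret=False: ev.junction_key(chrom, intron, strand, retention=ret)
    if etype == "RI":
        s, e = gene.introns("tB")[0] if len(iso_b) == 2 else gene.introns("tA")[0]
        return ev.ASEvent(
            "RI", gene.gene_id, chrom, strand, (s, e),
            frozenset({jk((s, e), ret=True)}), frozenset({jk((s, e))}),
        )
    if etype == "SE":
        cassette = next(x for x in iso_a if x not in iso_b)
        idx = iso_a.index(cassette)
        x, y = iso_a[idx - 1][1], iso_a[idx + 1][0]
        c, d = cassette
        return ev.ASEvent(
            "SE", gene.gene_id, chrom, strand, (x, c, d, y),
            frozenset({jk((x, c)), jk((d, y))}), frozenset({jk((x, y))}),
        )
    if etype in ("A5SS", "A3SS"):
        (i1,) = set(gene.introns("tA"))
        (i2,) = set(gene.introns("tB"))
        if i1[1] == i2[1]:
            alt1, alt2 = sorted((i1[0], i2[0]))
            shared = i1[1]
            short_intron, long_intron = (alt2, shared), (alt1, shared)
            side = "L"
        else:
            alt1, alt2 = sorted((i1[1], i2[1]))
            shared = i1[0]
            short_intron, long_intron = (shared, alt1), (shared, alt2)
            side = "R"
        return ev.ASEvent(
            etype, gene.gene_id, chrom, strand, (alt1, alt2, shared),
            frozenset({jk(short_intron)}), frozenset({jk(long_intron)}), side,
        )
    # MXE
    ea = next(x for x in iso_a if x not in iso_b)
    eb = next(x for x in iso_b if x not in iso_a)
    idx = iso_a.index(ea)
    x, y = iso_a[idx - 1][1], iso_a[idx + 1][0]
    if (strand == "+") == (ea[0] < eb[0]):
        up, dn = ea, eb
    else:
        up, dn = eb, ea
    return ev.ASEvent(
        "MXE", gene.gene_id, chrom, strand, (x, up[0], up[1], dn[0], dn[1], y),
        frozenset({jk((x, up[0])), jk((up[1], y))}),
        frozenset({jk((x, dn[0])), jk((dn[1], y))}),
    )


def make_toy_genome(
    n_genes: int,
    event_mix: dict[str, float] | None = None,
    seed: int = 0,
    exon_len_range: tuple[int, int] = (80, 200),
    intron_len_range: tuple[int, int] = (100, 300),
    ri_up_intron_len_range: tuple[int, int] = (50, 80),
    a5ss_offset_range: tuple[int, int] = (10, 60),
    a3ss_offset_range: tuple[int, int] = (6, 30),
    spacer: int = 100,
    minus_strand_fraction: float = 0.5,
    psi_control_range: tuple[float, float] = (0.3, 0.7),
    fraction_changed: float = 0.5,
    delta_psi_magnitude: float = 0.2,
    uss_control_range: tuple[float, float] = (0.6, 0.9),
    delta_uss_magnitude: float = 0.2,
    uss_change_strategy: str = "event_sites",
    chrom: str = "chrT",
) -> tuple[dict[str, str], list[GeneModel], SyntheticTruth]:
    """A toy genome in which each gene carries one designed AS event.

    Returns (genome mapping, gene models, truth).  A ``fraction_changed``
    subset of events receives a PSI shift of ``delta_psi_magnitude`` with a
    random sign in the mutant condition; RI events shifted upward draw their
    intron length from the short 50-80 nt band, the rest from the broad
    range.  Usage-truth changes are planted per ``uss_change_strategy``:
    ``event_sites`` (sites of changed events shift opposite to the event's
    retention change), ``ri_donors`` (all RI donors decrease), ``random``,
    or ``none``.
    """
    if n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    mix = dict(DEFAULT_EVENT_MIX if event_mix is None else event_mix)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ConfigError(f"event_mix proportions sum to {sum(mix.values())}, not 1")
    unknown = set(mix) - set(ev.EVENT_TYPES)
    if unknown:
        raise ConfigError(f"unknown event types in mix: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    types = list(mix)
    probs = np.array([mix[t] for t in types])

    seq_parts = [_rand_seq(rng, spacer)]
    pos = spacer
    models: list[GeneModel] = []
    truth_events: list[ev.ASEvent] = []
    ev_rows = []
    for i in range(n_genes):
        etype = types[int(rng.choice(len(types), p=probs))]
        strand = "-" if rng.random() < minus_strand_fraction else "+"
        changed = rng.random() < fraction_changed
        delta_sign = int(rng.choice([-1, 1])) if changed else 0
        gseq, iso_a, iso_b, _coords = _build_gene(rng, etype, delta_sign, dict(
            exon_len_range=exon_len_range,
            intron_len_range=intron_len_range,
            ri_up_intron_len_range=ri_up_intron_len_range,
            a5ss_offset_range=a5ss_offset_range,
            a3ss_offset_range=a3ss_offset_range,
        ))
        if strand == "-":
            gseq_final = revcomp(gseq)
        else:
            gseq_final = gseq
        L = len(gseq)
        gene = GeneModel(
            f"g{i:04d}",
            chrom,
            strand,
            {
                "tA": _map_intervals(iso_a, pos, L, strand),
                "tB": _map_intervals(iso_b, pos, L, strand),
            },
        )
        seq_parts.append(gseq_final)
        pos += L
        seq_parts.append(_rand_seq(rng, spacer))
        pos += spacer
        gene.validate()
        models.append(gene)
        event = _designed_event(gene, etype)
        truth_events.append(event)
        psi_c = float(rng.uniform(*psi_control_range))
        psi_m = float(np.clip(psi_c + delta_sign * delta_psi_magnitude, 0.0, 1.0))
        ev_rows.append(
            (event.event_id, gene.gene_id, etype, event.distance(), psi_c, psi_m, psi_m - psi_c)
        )
    genome = {chrom: "".join(seq_parts)}
    events_df = pd.DataFrame(
        ev_rows,
        columns=["event_id", "gene_id", "type", "distance", "psi_control", "psi_mutant", "delta_psi"],
    )

    sites = enumerate_splice_sites(models)
    changed_site_ids: dict[str, float] = {}
    if uss_change_strategy == "event_sites":
        for event, row in zip(truth_events, ev_rows):
            delta = row[6]
            if delta == 0:
                continue
            shift = -np.sign(delta) * delta_uss_magnitude
            for kind in (DONOR, "acceptor"):
                for sid in event_site_ids(event, kind):
                    changed_site_ids[sid] = shift
    elif uss_change_strategy == "ri_donors":
        for gene, event in zip(models, truth_events):
            if event.type != "RI":
                continue
            s, e = event.coords
            d, _a = intron_sites(gene.chrom, gene.strand, (s, e))
            changed_site_ids[d.site_id] = -delta_uss_magnitude
    elif uss_change_strategy == "random":
        for s in sites:
            if rng.random() < fraction_changed:
                changed_site_ids[s.site_id] = float(rng.choice([-1, 1])) * delta_uss_magnitude
    elif uss_change_strategy != "none":
        raise ConfigError(f"unknown uss_change_strategy {uss_change_strategy!r}")

    site_rows = []
    for s in sites:
        u_c = float(rng.uniform(*uss_control_range))
        shift = changed_site_ids.get(s.site_id, 0.0)
        u_m = float(np.clip(u_c + shift, 0.0, 1.0))
        site_rows.append((s.site_id, s.kind, u_c, u_m, shift != 0.0))
    sites_df = pd.DataFrame(
        site_rows, columns=["site_id", "kind", "uss_control", "uss_mutant", "changed"]
    )
    truth = SyntheticTruth(
        seed=int(seed),
        events=truth_events,
        events_df=events_df,
        sites_df=sites_df,
        params=dict(
            n_genes=n_genes,
            event_mix=mix,
            exon_len_range=list(exon_len_range),
            intron_len_range=list(intron_len_range),
            ri_up_intron_len_range=list(ri_up_intron_len_range),
            delta_psi_magnitude=delta_psi_magnitude,
            delta_uss_magnitude=delta_uss_magnitude,
            fraction_changed=fraction_changed,
            uss_change_strategy=uss_change_strategy,
        ),
    )
    truth.validate()
    return genome, models, truth


def simulate_counts(
    truth: SyntheticTruth,
    depth: float = 200.0,
    window_depth: float = 600.0,
    n_replicates: int = 3,
    seed: int = 0,
    conditions: tuple[str, str] = ("control", "mutant"),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Junction, event and coverage-window count tables for both conditions.

    Per event, sample and condition the event read total is Poisson(depth)
    and the inclusion count Binomial(total, true PSI); the inclusion count
    is split uniformly over the event's inclusion junctions (each simulated
    read supports exactly one junction) so that junction-count sums recover
    the event counts exactly.  Window counts per site are Poisson
    (window_depth) totals split binomially by the inverted usage formula, so
    the expected exonic share equals the true USS.

    Returns (event_counts, junction_counts, window_counts) long tables.
    """
    if depth < 1:
        raise ConfigError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    control, mutant = conditions
    ev_rows, jx_rows = [], []
    for event, (_, erow) in zip(truth.events, truth.events_df.iterrows()):
        incl = sorted(event.inclusion_junctions)
        skip = sorted(event.skipping_junctions)
        for cond, psi in ((control, erow["psi_control"]), (mutant, erow["psi_mutant"])):
            for r in range(n_replicates):
                sample = f"{cond}_{r + 1}"
                n = rng.poisson(depth)
                inc = rng.binomial(n, psi) if n > 0 else 0
                skp = n - inc
                ev_rows.append((event.event_id, sample, cond, int(inc), int(skp)))
                inc_split = rng.multinomial(inc, [1 / len(incl)] * len(incl))
                skp_split = rng.multinomial(skp, [1 / len(skip)] * len(skip))
                for key, cnt in zip(incl, inc_split):
                    jx_rows.append((key, sample, cond, int(cnt)))
                for key, cnt in zip(skip, skp_split):
                    jx_rows.append((key, sample, cond, int(cnt)))
    win_rows = []
    for _, srow in truth.sites_df.iterrows():
        for cond, uss in ((control, srow["uss_control"]), (mutant, srow["uss_mutant"])):
            for r in range(n_replicates):
                sample = f"{cond}_{r + 1}"
                n = rng.poisson(window_depth)
                ea, _eb = expected_counts_for_uss(uss, 1.0)
                a = rng.binomial(n, ea) if n > 0 else 0
                win_rows.append((srow["site_id"], sample, cond, int(a), int(n - a)))
    event_counts = pd.DataFrame(ev_rows, columns=["event_id", "sample", "condition", "inclusion", "skipping"])
    junction_counts = pd.DataFrame(jx_rows, columns=["junction", "sample", "condition", "count"])
    window_counts = pd.DataFrame(
        win_rows, columns=["site_id", "sample", "condition", "exonic_count", "intronic_count"]
    )
    return event_counts, junction_counts, window_counts


def simulate_lariat_reads(
    intron_ref: IntronRef,
    bp_freqs: dict[int, float],
    n_clones: int = 12,
    a2t_rate: float = 0.7,
    error_rate: float = 0.005,
    rc_fraction: float = 0.5,
    l1_range: tuple[int, int] = (10, 16),
    l2_range: tuple[int, int] = (10, 16),
    min_anchor: int = 8,
    seed: int = 0,
    strain: str = "WT",
) -> tuple[LariatReadSet, pd.DataFrame]:
    """Subclone reads from a lariat of one intron.

    Each read is intron[bp - L1 + 1 .. bp] ++ intron[1 .. L2] in sense
    orientation, anchor lengths drawn uniformly from the given ranges
    (clipped so the pre-jump anchor stays inside the intron).  If the branch
    base is A it is replaced by T with probability ``a2t_rate``; every other
    position suffers a uniform substitution error at ``error_rate``; a
    ``rc_fraction`` share of reads is emitted reverse-complemented (cloning
    orientation is arbitrary).  Returns the read set and a per-read truth
    table (read_id, bp_offset, orientation, a_to_t).
    """
    total = sum(bp_freqs.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"bp_freqs sum to {total}, not 1")
    Li = intron_ref.length
    seq = intron_ref.sequence
    for off in bp_freqs:
        j = intron_ref.offset_to_index(off)
        if j + 1 < min_anchor or Li - j - 1 < min_anchor:
            raise ConfigError(
                f"BP offset {off} is closer than min_anchor={min_anchor} to an intron end"
            )
    rng = np.random.default_rng(seed)
    offsets = sorted(bp_freqs)
    probs = np.array([bp_freqs[o] for o in offsets])
    reads, truth_rows = [], []
    for i in range(n_clones):
        off = offsets[int(rng.choice(len(offsets), p=probs))]
        j = intron_ref.offset_to_index(off)
        l1 = int(rng.integers(min(l1_range[0], j + 1), min(l1_range[1], j + 1) + 1))
        l2 = int(rng.integers(min(l2_range[0], Li), min(l2_range[1], Li) + 1))
        pre = list(seq[j - l1 + 1 : j + 1])
        post = list(seq[:l2])
        a2t = False
        if pre[-1] == "A" and rng.random() < a2t_rate:
            pre[-1] = "T"
            a2t = True
        bases = pre + post
        for p in range(len(bases)):
            if p == l1 - 1:
                continue  # the branch base carries only the A->T signature
            if rng.random() < error_rate:
                choices = [b for b in "ACGT" if b != bases[p]]
                bases[p] = choices[int(rng.integers(3))]
        read = "".join(bases)
        orientation = "reverse-complement" if rng.random() < rc_fraction else "as-is"
        if orientation == "reverse-complement":
            read = revcomp(read)
        rid = f"{intron_ref.intron_id}|{strain}|clone{i + 1:05d}"
        reads.append((rid, read))
        truth_rows.append((rid, off, orientation, a2t))
    truth_df = pd.DataFrame(truth_rows, columns=["read_id", "bp_offset", "orientation", "a_to_t"])
    return LariatReadSet(intron_ref.intron_id, strain, reads), truth_df


def random_intron(rng: np.random.Generator, length: int, canonical: bool = True) -> str:
    """Uniform random intron sequence, optionally with GT...AG ends."""
    s = _rand_seq(rng, length)
    if canonical and length >= 4:
        s = "GT" + s[2:-2] + "AG"
    return s
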