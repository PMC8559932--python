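"""End-to-end orchestration: simulate -> quantify -> screen -> enrich -> lariat.

A run is driven by a RunConfig (YAML-loadable).  Each stochastic stage
receives a seed derived deterministically from the single global seed, so a
rerun with an identical config reproduces every output bit-identically.
Every emitted file is recorded in a JSON manifest with its SHA-256 checksum,
the full parameter set, the derived per-stage seeds and warning tallies.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import lariat as lb
from . import simulate as sim
from . import strength as st
from . import usage as us
from .annotation import DONOR, SpliceSite, fetch_window, write_fasta, write_gtf

log = logging.getLogger("lariatuss")

STAGES = ("genome", "counts", "psi", "uss", "strength", "lariat")


@dataclass
class RunConfig:
    """Thresholds default to the screen's contract: |dPSI| > 0.05, FDR <
    0.05, supporting reads >= 5; |dUSS| > 0.01; 40-nt coverage windows;
    lariat calling with min_anchor 8, max_mismatch 1; branch A-to-T misread
    rate 0.7."""

    seed: int = 0
    outdir: str = "lariatuss_run"
    n_genes: int = 60
    depth: float = 200.0
    window_depth: float = 600.0
    n_replicates: int = 3
    delta_psi_threshold: float = 0.05
    fdr_threshold: float = 0.05
    min_reads: int = 5
    delta_uss_threshold: float = 0.01
    window: int = 40
    min_anchor: int = 8
    max_mismatch: int = 1
    a2t_rate: float = 0.7
    lariat_error_rate: float = 0.005
    lariat_n_clones: int = 12
    lariat_intron_length: int = 80
    lariat_bp_freqs: dict = field(
        default_factory=lambda: {
            "WT": {-25: 0.6, -54: 0.4},
            "mutant": {-25: 0.2, -54: 0.8},
        }
    )
    genome_fasta: str | None = None  # optional user inputs; simulated when absent
    annotation_gtf: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in data.items()})
        if "lariat_bp_freqs" in data:
            cfg.lariat_bp_freqs = {
                strain: {int(k): float(v) for k, v in freqs.items()}
                for strain, freqs in data["lariat_bp_freqs"].items()
            }
        return cfg

    def validate(self) -> list[str]:
        failures = []
        for name in (
            "delta_psi_threshold",
            "fdr_threshold",
            "delta_uss_threshold",
            "window",
            "min_anchor",
            "depth",
        ):
            if getattr(self, name) <= 0:
                failures.append(f"{name} must be positive")
        if self.min_reads < 0 or self.max_mismatch < 0:
            failures.append("min_reads and max_mismatch must be non-negative")
        for path_attr in ("genome_fasta", "annotation_gtf"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                failures.append(f"{path_attr} path does not exist: {p}")
        for strain, freqs in self.lariat_bp_freqs.items():
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                failures.append(f"lariat_bp_freqs[{strain}] do not sum to 1")
        return failures


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(seed, spawn_key=(idx,))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_inputs(config: RunConfig) -> list[str]:
    """Schema checks on any user-supplied inputs plus config validation.

    Returns a list of named failures (empty when everything checks out).
    """
    failures = config.validate()
    if config.annotation_gtf and not failures:
        from .annotation import AnnotationError, load_annotation, read_fasta

        genome = read_fasta(config.genome_fasta) if config.genome_fasta else None
        try:
            load_annotation(config.annotation_gtf, genome=genome)
        except AnnotationError as exc:
            failures.append(f"annotation: {exc}")
    return failures


def check_count_table(df: pd.DataFrame, kind: str, known_junctions=None, known_sites=None) -> list[str]:
    """Cross-check a count table against the annotation-derived keys."""
    failures = []
    if kind == "junction":
        for col in ("junction", "sample", "condition", "count"):
            if col not in df.columns:
                failures.append(f"junction table missing column {col}")
                return failures
        if (df["count"] < 0).any():
            failures.append("junction table has negative counts")
        if known_junctions is not None:
            unknown = set(df["junction"]) - set(known_junctions)
            for key in sorted(unknown)[:10]:
                failures.append(f"junction key not resolvable against annotation: {key}")
    elif kind == "window":
        for col in ("site_id", "sample", "condition", "exonic_count", "intronic_count"):
            if col not in df.columns:
                failures.append(f"window table missing column {col}")
                return failures
        if (df[["exonic_count", "intronic_count"]] < 0).any().any():
            failures.append("window table has negative counts")
        if known_sites is not None:
            unknown = set(df["site_id"]) - set(known_sites)
            for key in sorted(unknown)[:10]:
                failures.append(f"site_id not resolvable against annotation: {key}")
    return failures


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in dependency order; returns the manifest dict."""
    failures = validate_inputs(config)
    if failures:
        raise ValueError("config validation failed: " + "; ".join(failures))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {"config": asdict(config), "stages": {}, "files": {}, "warnings": {}}

    def record(stage: str, name: str, path: Path):
        manifest["files"][str(path.relative_to(out))] = _sha256(path)
        manifest["stages"].setdefault(stage, []).append(str(path.relative_to(out)))
        log.info("%s: wrote %s", stage, path)

    try:
        # -- genome ---------------------------------------------------------
        seed = stage_seed(config.seed, "genome")
        manifest.setdefault("seeds", {})["genome"] = seed
        genome, models, truth = sim.make_toy_genome(config.n_genes, seed=seed)
        write_fasta(genome, out / "genome.fa")
        write_gtf(models, out / "annotation.gtf")
        truth.to_json(out / "truth.json")
        for name in ("genome.fa", "annotation.gtf", "truth.json"):
            record("genome", name, out / name)

        # -- counts ---------------------------------------------------------
        seed = stage_seed(config.seed, "counts")
        manifest["seeds"]["counts"] = seed
        event_counts, junction_counts, window_counts = sim.simulate_counts(
            truth,
            depth=config.depth,
            window_depth=config.window_depth,
            n_replicates=config.n_replicates,
            seed=seed,
        )
        event_counts.to_csv(out / "event_counts.tsv", sep="\t", index=False)
        junction_counts.to_csv(out / "junction_counts.tsv", sep="\t", index=False)
        window_counts.to_csv(out / "window_counts.tsv", sep="\t", index=False)
        for name in ("event_counts.tsv", "junction_counts.tsv", "window_counts.tsv"):
            record("counts", name, out / name)

        # -- psi ------------------------------------------------------------
        events = ev.extract_events(models)
        psi_table = ev.differential_psi(
            event_counts,
            events,
            delta_threshold=config.delta_psi_threshold,
            fdr_threshold=config.fdr_threshold,
            min_reads=config.min_reads,
        )
        psi_table.to_csv(out / "psi_screen.tsv", sep="\t", index=False)
        record("psi", "psi_screen.tsv", out / "psi_screen.tsv")
        manifest["warnings"]["untestable_events"] = int((~psi_table["testable"]).sum())
        dist_rows = []
        for direction in ("increased", "decreased"):
            dist_df, hists = ev.distance_distribution(
                psi_table, events, direction=direction, delta_threshold=config.delta_psi_threshold
            )
            dist_df["direction"] = direction
            dist_rows.append(dist_df)
        pd.concat(dist_rows).to_csv(out / "distances.tsv", sep="\t", index=False)
        record("psi", "distances.tsv", out / "distances.tsv")

        # -- uss -------------------------------------------------------------
        uss_table = us.differential_uss(
            window_counts,
            delta_threshold=config.delta_uss_threshold,
            fdr_threshold=config.fdr_threshold,
        )
        uss_table.to_csv(out / "uss_screen.tsv", sep="\t", index=False)
        record("uss", "uss_screen.tsv", out / "uss_screen.tsv")
        manifest["warnings"]["untestable_sites"] = int((~uss_table["testable"]).sum())
        enrich = us.uss_event_enrichment(uss_table, events, psi_table, config.fdr_threshold)
        enrich.to_csv(out / "uss_enrichment.tsv", sep="\t", index=False)
        record("uss", "uss_enrichment.tsv", out / "uss_enrichment.tsv")

        # -- strength --------------------------------------------------------
        groups = st.groups_from_uss(uss_table, config.delta_uss_threshold)
        rows = []
        for sid, group in zip(uss_table["site_id"], groups):
            site = SpliceSite.from_id(sid)
            ex, ib = st.WINDOW_SPLIT[site.kind]
            try:
                window = fetch_window(genome, site, ex, ib)
            except Exception:
                continue
            rows.append((sid, site.kind, window, group))
        win_df = pd.DataFrame(rows, columns=["site_id", "kind", "window_seq", "group"])
        score_frames = []
        for kind in (DONOR, "acceptor"):
            sub = win_df[win_df["kind"] == kind]
            if len(sub) == 0:
                continue
            model = st.train_model(list(sub["window_seq"]), kind)
            st.write_model(model, out / f"pwm_{kind}.tsv")
            record("strength", f"pwm_{kind}.tsv", out / f"pwm_{kind}.tsv")
            scored = sub.copy()
            scored["score"] = st.score_many(model, list(sub["window_seq"]))
            score_frames.append(scored)
        scores = pd.concat(score_frames) if score_frames else win_df.assign(score=np.nan)
        st.write_score_table(scores.drop(columns=["window_seq"]), out / "site_scores.tsv")
        record("strength", "site_scores.tsv", out / "site_scores.tsv")
        summary, pairs = st.summarize_by_group(scores.dropna(subset=["group"]))
        summary.to_csv(out / "score_summary.tsv", sep="\t", index=False)
        pairs.to_csv(out / "score_tests.tsv", sep="\t", index=False)
        record("strength", "score_summary.tsv", out / "score_summary.tsv")
        record("strength", "score_tests.tsv", out / "score_tests.tsv")

        # -- lariat ----------------------------------------------------------
        seed = stage_seed(config.seed, "lariat")
        manifest["seeds"]["lariat"] = seed
        rng = np.random.default_rng(seed)
        intron = lb.IntronRef("sim_intron", sim.random_intron(rng, config.lariat_intron_length))
        write_fasta({"sim_intron": intron.sequence}, out / "lariat_intron.fa")
        record("lariat", "lariat_intron.fa", out / "lariat_intron.fa")
        n_amb_total = 0
        usage_frames = []
        for strain, freqs in config.lariat_bp_freqs.items():
            readset, _rt = sim.simulate_lariat_reads(
                intron,
                freqs,
                n_clones=config.lariat_n_clones,
                a2t_rate=config.a2t_rate,
                error_rate=config.lariat_error_rate,
                min_anchor=config.min_anchor,
                seed=int(rng.integers(0, 2**31 - 1)),
                strain=strain,
            )
            readset.to_fasta(out / f"lariat_reads_{strain}.fa")
            record("lariat", f"lariat_reads_{strain}.fa", out / f"lariat_reads_{strain}.fa")
            calls = lb.call_reads(readset.reads, intron, config.min_anchor, config.max_mismatch)
            lb.calls_to_frame(calls).to_csv(out / f"bp_calls_{strain}.tsv", sep="\t", index=False)
            record("lariat", f"bp_calls_{strain}.tsv", out / f"bp_calls_{strain}.tsv")
            table = lb.aggregate_bp(calls, intron, strain)
            n_amb_total += table.n_ambiguous
            frame = table.table.copy()
            frame.insert(0, "strain", strain)
            usage_frames.append(frame)
        pd.concat(usage_frames).to_csv(out / "bp_usage.tsv", sep="\t", index=False)
        record("lariat", "bp_usage.tsv", out / "bp_usage.tsv")
        manifest["warnings"]["ambiguous_bp_calls"] = n_amb_total
    except Exception as exc:
        manifest["failed_stage"] = _current_stage(manifest)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        log.removeHandler(handler)
        raise RuntimeError(f"pipeline aborted in stage {manifest['failed_stage']}: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.removeHandler(handler)
    handler.close()
    return manifest


def _current_stage(manifest: dict) -> str:
    done = list(manifest["stages"])
    remaining = [s for s in STAGES if s not in done]
    return remaining[0] if remaining else done[-1]
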