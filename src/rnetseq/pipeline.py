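"""End-to-end orchestration: simulate -> call -> diff -> register ->
score distribution -> sequence features -> polarity, with a truth-recovery
report when the input is simulated.

A run is driven by one :class:`RunConfig` (loadable from YAML); every stage
writes its artifact into the output directory and a manifest records
parameters and input checksums so identical configs reproduce identical
artifacts byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, io_formats, pause_calling, polarity, register, scoredist
from . import seqfeatures
from .io_formats import ReadSet
from .synthetic import SimConfig, simulate_genome, simulate_reads

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Either ``simulate=True`` (a genome and condition-paired reads are
    generated from ``sim``) or paths to a genome FASTA, a GFF3 annotation
    and per-condition BED6 read files must be given.
    """

    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    genome_path: str | None = None
    features_path: str | None = None
    reads_wt_path: str | None = None
    reads_dep_path: str | None = None
    # thresholds
    min_score: float = 20.0
    min_count: int = 10
    cluster_radius: int = 2
    window_half: int = 100
    pseudocount: float = 1.0
    bin_width: float = 50.0
    delta_threshold: float = 0.1
    hairpin_stem_min: int = 5
    hairpin_loop_range: tuple[int, int] = (3, 8)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if "hairpin_loop_range" in raw:
            raw["hairpin_loop_range"] = tuple(raw["hairpin_loop_range"])
        for key in ("class_mixture", "register_mixture", "hairpin_distance_range"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        try:
            return cls(sim=SimConfig(**sim_raw), **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def validate(self) -> None:
        if not self.simulate:
            for name in ("genome_path", "features_path", "reads_wt_path",
                         "reads_dep_path"):
                p = getattr(self, name)
                if p is None:
                    raise ConfigError(f"non-simulation mode requires {name}")
                if not Path(p).exists():
                    raise ConfigError(f"{name}: {p} does not exist")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage; returns a dict of artifact paths and counts."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # --- inputs -------------------------------------------------------
        stage = "simulate" if config.simulate else "load"
        if config.simulate:
            genome, features, truth = simulate_genome(config.sim)
            reads = {
                "WT": simulate_reads(truth, "WT", config.sim, config.sim.seed + 1),
                "depleted": simulate_reads(truth, "depleted", config.sim,
                                           config.sim.seed + 2),
            }
            io_formats.write_genome([genome], outdir / "genome.fasta")
            io_formats.write_features(features, outdir / "features.gff3")
            truth_out = truth.copy()
            truth_out["position_1based"] = truth_out.pop("position") + 1
            _write_tsv(truth_out, outdir / "truth.tsv")
            for cond, rs in reads.items():
                rs.to_bed(outdir / f"reads_{cond}.bed")
        else:
            genomes = io_formats.read_genome(config.genome_path)
            genome = next(iter(genomes.values()))
            features = io_formats.read_features(config.features_path)
            reads = {"WT": ReadSet.from_bed(config.reads_wt_path),
                     "depleted": ReadSet.from_bed(config.reads_dep_path)}
            truth = None

        # --- per-condition calling ---------------------------------------
        stage = "call"
        coverage, pauses = {}, {}
        for cond, rs in reads.items():
            cov = pause_calling.pileup_3prime_ends(rs, len(genome), genome.id)
            called = pause_calling.call_pauses(
                cov, config.min_score, config.min_count,
                config.cluster_radius, config.window_half)
            called = pause_calling.annotate_pauses(called, features)
            coverage[cond] = cov
            pauses[cond] = called
            _write_tsv(pause_calling.pauses_to_frame(called),
                       outdir / f"pauses_{cond}.tsv")
            io_formats.write_bedgraph(genome.id, cov.plus,
                                      outdir / f"coverage_{cond}.plus.bedgraph")
            io_formats.write_bedgraph(genome.id, cov.minus,
                                      outdir / f"coverage_{cond}.minus.bedgraph")
            log.info("%s: %d reads -> %d pauses", cond, len(rs), len(called))

        # --- differential -------------------------------------------------
        stage = "diff"
        matched = differential.match_pause_sets(
            pauses["WT"], pauses["depleted"], coverage["WT"], coverage["depleted"],
            union=True, window_half=config.window_half)
        exclude = list(zip(matched["strand"], matched["position"]))
        tpm = {cond: differential.compute_tpm(coverage[cond], features, exclude)
               for cond in reads}
        diff = differential.differential_table(matched, tpm["WT"], tpm["depleted"],
                                               config.pseudocount)
        diff_out = diff.copy()
        diff_out.insert(0, "position_1based", diff_out.pop("position") + 1)
        _write_tsv(diff_out, outdir / "diff.tsv")

        # --- register ------------------------------------------------------
        stage = "register"
        reg = {}
        for cond in reads:
            sites = [(int(p), s) for p, s in zip(matched["position"],
                                                 matched["strand"])]
            reg[cond] = register.register_table(reads[cond], sites)
            _write_tsv(reg[cond], outdir / f"register_{cond}.tsv")
        merged = reg["WT"].merge(reg["depleted"], on=["position_1based", "strand"],
                                 suffixes=("_wt", "_dep"))
        if len(merged):
            merged["backtrack_change"] = register.group_by_backtrack_change(
                merged["frac_backtracked_wt"], merged["frac_backtracked_dep"],
                config.delta_threshold)
            _write_tsv(merged[["position_1based", "strand", "frac_backtracked_wt",
                               "frac_backtracked_dep", "backtrack_change"]],
                       outdir / "backtrack_change.tsv")

        # --- score distribution -------------------------------------------
        stage = "scoredist"
        fits = {}
        for cond, called in pauses.items():
            scores = [p.score for p in called]
            try:
                fit = scoredist.fit_negative_exponential(scores, config.bin_width)
                fits[cond] = fit.to_dict()
            except scoredist.FitError as exc:
                fits[cond] = {"error": str(exc)}
        (outdir / "scoredist.json").write_text(json.dumps(fits, indent=2))

        # --- sequence features --------------------------------------------
        stage = "seqfeatures"
        suppressed = diff[diff["pause_class"] == "suppressed"]
        sup_sites = {(int(p), s) for p, s in zip(suppressed["position"],
                                                 suppressed["strand"])}
        sup_pauses = [p for cond in ("depleted",) for p in pauses[cond]
                      if (p.position, p.strand) in sup_sites]
        hairpin_profile = None
        windows = seqfeatures.extract_windows(genome, sup_pauses)
        if windows:
            pfm = seqfeatures.build_pfm(windows)
            pfm.to_frame().to_csv(outdir / "pfm_suppressed.tsv", sep="\t")
            long_windows = seqfeatures.extract_windows(genome, sup_pauses,
                                                       upstream=30, downstream=0)
            hairpin_profile = seqfeatures.hairpin_distance_profile(
                [w.upstream_seq for w in long_windows],
                stem_min=config.hairpin_stem_min,
                loop_range=config.hairpin_loop_range,
                seed=config.seed)
            hairpin_profile.to_csv(outdir / "hairpin_profile.tsv", sep="\t")

        # --- polarity ------------------------------------------------------
        stage = "polarity"
        for cond in reads:
            _write_tsv(polarity.polarity_table(coverage[cond], features),
                       outdir / f"polarity_{cond}.tsv")
            try:
                prof = polarity.metagene_profile(coverage[cond], features)
                pd.DataFrame({"bin": np.arange(len(prof)),
                              "mean_normalized_coverage": prof}
                             ).to_csv(outdir / f"metagene_{cond}.tsv",
                                      sep="\t", index=False)
            except ValueError:
                log.warning("%s: no usable genes for metagene profile", cond)

        # --- evaluation & manifest ----------------------------------------
        stage = "evaluate"
        report = None
        if truth is not None:
            report = evaluate_against_truth(
                diff, pauses, reg, truth,
                scoredist_fit=fits.get("WT"),
                planted_rate=config.sim.base_strength_rate,
                hairpin_profile=hairpin_profile)
            (outdir / "report.json").write_text(json.dumps(report, indent=2))

        manifest = {
            "config": _config_dict(config),
            "counts": {
                "reads": {cond: len(rs) for cond, rs in reads.items()},
                "pauses": {cond: len(ps) for cond, ps in pauses.items()},
                "matched": int(len(matched)),
                "shared": int(matched["shared"].sum()) if len(matched) else 0,
                "classes": diff["pause_class"].value_counts().to_dict()
                           if len(diff) else {},
            },
            "input_checksums": {
                name: _sha256(outdir / name)
                for name in ("genome.fasta", "features.gff3")
                if (outdir / name).exists()
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         sort_keys=True))
        return {"outdir": str(outdir), "report": report,
                "counts": manifest["counts"]}
    except (ConfigError,):
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=str))


def evaluate_against_truth(diff: pd.DataFrame, pauses: dict, reg: dict,
                           truth: pd.DataFrame,
                           recall_min_weight: float = 30.0,
                           scoredist_fit: dict | None = None,
                           planted_rate: float | None = None,
                           hairpin_profile: pd.DataFrame | None = None) -> dict:
    """Truth-recovery metrics for a simulated run.

    A planted pause is recovered when a call exists at its exact
    (position, strand).  Precision counts any called position present in
    the truth as a true positive; recall is reported over planted pauses
    whose WT excess weight is at least ``recall_min_weight`` (weaker
    plants sit below the calling thresholds by design).  When the score
    fit, the planted weight rate or the hairpin profile are supplied, the
    report also contains the score-decay-rate error (the score tail decays
    at the planted exponential rate) and the modal hairpin distance versus
    the planted one.
    """
    if truth is None or len(truth) == 0:
        return {"empty_truth": True}
    truth_keys = set(zip(truth["position"], truth["strand"]))
    called_keys = {(p.position, p.strand) for p in pauses["WT"]}
    tp = len(called_keys & truth_keys)
    precision = tp / len(called_keys) if called_keys else float("nan")
    strong = truth[truth["weight_wt"] >= recall_min_weight]
    strong_keys = set(zip(strong["position"], strong["strand"]))
    recall = (len(called_keys & strong_keys) / len(strong_keys)
              if strong_keys else float("nan"))

    # classification metrics over matched pauses
    merged = diff.merge(truth, on=["position", "strand"],
                        suffixes=("", "_truth"))
    out_class = {}
    if len(merged):
        for cls, grp in merged.groupby("pause_class_truth"):
            est = grp["log2fc"].mean()
            acc = float((grp["pause_class"] == cls).mean())
            out_class[cls] = {"n": int(len(grp)), "mean_log2fc": float(est),
                              "class_accuracy": acc}

    # register recovery (WT condition)
    reg_mae = float("nan")
    reg_wt = reg.get("WT")
    if reg_wt is not None and len(reg_wt):
        r = reg_wt.copy()
        r["position"] = r["position_1based"] - 1
        m = r.merge(truth, on=["position", "strand"])
        if len(m):
            err = (np.abs(m["frac_post_x"] - m["frac_post_y"])
                   + np.abs(m["frac_pre_x"] - m["frac_pre_y"])
                   + np.abs(m["frac_backtracked_x"] - m["frac_backtracked_y"])) / 3
            reg_mae = float(err.mean())

    report = {
        "pause_precision": precision,
        "pause_recall": recall,
        "n_called": len(called_keys),
        "n_planted": len(truth_keys),
        "classes": out_class,
        "register_mae": reg_mae,
    }
    if scoredist_fit and planted_rate and "lambda_hat" in scoredist_fit:
        lam = scoredist_fit["lambda_hat"]
        report["scoredist_rate_rel_err"] = abs(lam - planted_rate) / planted_rate
    if hairpin_profile is not None and len(hairpin_profile):
        modal = int(hairpin_profile["real_count"].idxmax())
        planted_d = truth.loc[truth["hairpin"], "hairpin_distance"]
        report["hairpin_modal_distance"] = modal
        if len(planted_d):
            report["hairpin_planted_modal_distance"] = int(planted_d.mode().iloc[0])
    return report
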