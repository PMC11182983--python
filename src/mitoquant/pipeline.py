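"""End-to-end orchestration: simulate -> quantify -> concordance -> regress.

A run is driven by a :class:`RunConfig` (YAML-loadable), executes the
requested stages in dependency order inside one output directory, and
records a JSON manifest (seed, config hash, per-stage row counts, package
version). One global seed deterministically spawns per-stage substreams, so
identical config + seed gives byte-identical report CSVs and stages can be
re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concordance import (
    biopsies_to_frame,
    mann_whitney_u,
    pairwise_site_concordance,
    read_biopsies_csv,
    site_summary,
)
from .genome import make_bins, toy_genome
from .qpcr import compute_qpcr_ratio, read_plates_csv, results_to_frame
from .quant import (
    BinCountMatrix,
    NormalizationInterval,
    QcConfig,
    compute_mtdna_ratio,
    count_bin_reads,
    filter_reads,
    ratios_to_frame,
    screen_normalization_interval,
)
from .reads import write_sam
from .regression import (
    DEFAULT_LINEAR_FEATURES,
    DEFAULT_LINEAR_INTERACTIONS,
    ENDPOINTS,
    feature_screen,
    fit_ratio_model,
    read_timelapse_csv,
    read_transfers_csv,
    run_endpoint_models,
    timelapse_to_frame,
    transfers_to_frame,
)
from .simulate import (
    CohortEffectSpec,
    SimReadConfig,
    simulate_biopsy_reads,
    simulate_multibiopsy_set,
    simulate_qpcr_plate,
    simulate_transfer_cohort,
    simulate_timelapse_cohort,
)

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

#: Canonical stage order; selection is any subset, executed in this order.
STAGES = ("simulate", "screen", "quantify", "qpcr", "concordance", "regress", "report")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``quant``, ``biopsy``, ``qpcr`` and ``cohort`` hold per-stage settings;
    unknown keys are rejected so config typos fail before any stage runs.
    """

    outdir: str | Path = "mitoquant_run"
    seed: int = 0
    stages: Sequence[str] = STAGES
    quant: dict[str, Any] = field(default_factory=dict)
    biopsy: dict[str, Any] = field(default_factory=dict)
    qpcr: dict[str, Any] = field(default_factory=dict)
    cohort: dict[str, Any] = field(default_factory=dict)
    scale: float = 1.0

    _QUANT_KEYS = {
        "n_samples", "n_reference", "nuclear_coverage", "bin_size",
        "window_bins", "mt_copies", "genome_scale", "qc", "write_sam_demo",
    }
    _BIOPSY_KEYS = {"n_embryos", "within_embryo_sd", "between_embryo_sd",
                    "icm_shift", "icm_extra_sd", "amp_fail_rate", "n_media_pairs"}
    _QPCR_KEYS = {"true_ratios", "ct_noise_sd", "n_replicates"}

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        self.stages = [s for s in STAGES if s in set(self.stages)]
        for name, keys in (("quant", self._QUANT_KEYS), ("biopsy", self._BIOPSY_KEYS),
                           ("qpcr", self._QPCR_KEYS)):
            bad = set(getattr(self, name)) - keys
            if bad:
                raise ValueError(f"unknown {name} config keys: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_dict(self) -> dict[str, Any]:
        return {
            "outdir": str(self.outdir), "seed": self.seed, "stages": list(self.stages),
            "quant": dict(self.quant), "biopsy": dict(self.biopsy),
            "qpcr": dict(self.qpcr), "cohort": dict(self.cohort), "scale": self.scale,
        }

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream below 2**31."""
    child = np.random.SeedSequence(global_seed).spawn(len(STAGES))[STAGES.index(stage)]
    return int(child.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the selected stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages": {},
    }

    try:
        for stage in config.stages:
            runner = _STAGE_RUNNERS[stage]
            manifest["stages"][stage] = runner(config, outdir)
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "partial"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(manifest, outdir)
        raise

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict[str, Any], outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _quant_settings(config: RunConfig) -> dict[str, Any]:
    q = {
        "n_samples": 4, "n_reference": 12, "nuclear_coverage": 40.0,
        "bin_size": 100_000, "window_bins": 10,
        "mt_copies": [600.0, 1000.0, 1600.0, 2400.0],
        "genome_scale": 100, "qc": {}, "write_sam_demo": True,
    }
    q.update(config.quant)
    return q


def _stage_simulate(config: RunConfig, outdir: Path) -> dict[str, Any]:
    seed = _stage_seed(config.seed, "simulate")
    counts: dict[str, Any] = {}

    # multi-biopsy embryo set (+ paired biopsy/media records)
    b = {"n_embryos": 29, "within_embryo_sd": 0.15, "between_embryo_sd": 0.50,
         "icm_shift": 0.26, "amp_fail_rate": 0.05, "n_media_pairs": 14}
    b.update(config.biopsy)
    n_media = b.pop("n_media_pairs")
    records = simulate_multibiopsy_set(seed=seed, **b)
    biopsies_to_frame(records).to_csv(outdir / "biopsies.csv", index=False)
    counts["biopsies"] = len(records)

    rng = np.random.default_rng(seed + 1)
    media = pd.DataFrame(
        {
            "pair_id": [f"M{i + 1:03d}" for i in range(n_media)],
            "biopsy_ratio": rng.lognormal(math.log(2.5), 0.5, size=n_media),
            "media_ratio": rng.lognormal(math.log(0.05), 0.8, size=n_media),
        }
    )
    media.to_csv(outdir / "media_pairs.csv", index=False)
    counts["media_pairs"] = n_media

    # qPCR plates
    qp = {"true_ratios": [0.5, 1.0, 2.5, 8.0], "ct_noise_sd": 0.25, "n_replicates": 3}
    qp.update(config.qpcr)
    rows = []
    for i, ratio in enumerate(qp["true_ratios"]):
        plate = simulate_qpcr_plate(
            ratio, ct_noise_sd=qp["ct_noise_sd"], n_replicates=qp["n_replicates"],
            seed=seed + 100 + i, sample_id=f"Q{i + 1:02d}",
        )
        for gene in ("ND1", "BECN1", "ND6", "NEB"):
            for rep, ct in enumerate(plate.cts(gene)):
                rows.append({"sample_id": plate.sample_id, "gene": gene,
                             "replicate": rep + 1, "ct": ct,
                             "true_ratio": ratio})
    pd.DataFrame(rows).to_csv(outdir / "qpcr_plates.csv", index=False)
    counts["qpcr_plates"] = len(qp["true_ratios"])

    # clinical cohorts
    cohort_kwargs = dict(config.cohort)
    n_transfer = cohort_kwargs.pop("n_transfer", 2283)
    spec = CohortEffectSpec(seed=seed + 200, **cohort_kwargs)
    timelapse = simulate_timelapse_cohort(spec)
    timelapse_to_frame(timelapse).to_csv(outdir / "timelapse.csv", index=False)
    counts["timelapse"] = len(timelapse)

    transfer_spec = CohortEffectSpec(seed=seed + 300,
                                     **{**cohort_kwargs, "n": n_transfer})
    transfers = simulate_transfer_cohort(transfer_spec)
    transfers_to_frame(transfers).to_csv(outdir / "transfers.csv", index=False)
    counts["transfers"] = len(transfers)

    # read sets: reference panel (euploid) + quantification samples
    q = _quant_settings(config)
    genome = toy_genome(scale=q["genome_scale"])
    bins = make_bins(genome, bin_size=q["bin_size"])
    truth_rows = []
    demo_written = False
    for group, n, copies_list in (
        ("ref", q["n_reference"], None),
        ("sample", q["n_samples"], q["mt_copies"]),
    ):
        for i in range(n):
            copies = 1000.0 if copies_list is None else copies_list[i % len(copies_list)]
            sim_config = SimReadConfig(
                mt_copies_per_cell=copies, nuclear_coverage=q["nuclear_coverage"],
                seed=seed + 1000 + (0 if group == "ref" else 500) + i,
            )
            sim = simulate_biopsy_reads(sim_config, bins, genome=genome)
            _READ_CACHE[(id(config), group, i)] = (sim, bins, genome)
            truth_rows.append(
                {"group": group, "sample_id": f"{group}{i + 1:02d}",
                 "mt_copies_per_cell": copies,
                 "true_mt_per_bin_ratio": sim.true_mt_per_bin_ratio,
                 "n_reads": len(sim.reads), "seed": sim_config.seed}
            )
            if group == "sample" and q["write_sam_demo"] and not demo_written:
                write_sam(sim.reads, outdir / "sample01.sam", genome)
                demo_written = True
    pd.DataFrame(truth_rows).to_csv(outdir / "read_truth.csv", index=False)
    counts["read_sets"] = len(truth_rows)
    return counts


# in-memory hand-off of simulated read sets between stages of one process
_READ_CACHE: dict[tuple, Any] = {}


def _counts_for(config: RunConfig, group: str, n: int) -> BinCountMatrix:
    q = _quant_settings(config)
    qc = QcConfig(**q["qc"])
    mats = []
    for i in range(n):
        key = (id(config), group, i)
        if key not in _READ_CACHE:
            raise RuntimeError("simulate stage must run before quantification stages")
        sim, bins, _genome = _READ_CACHE[key]
        retained, stats = filter_reads(sim.reads, qc)
        mats.append(
            count_bin_reads(retained, bins, sample_id=f"{group}{i + 1:02d}",
                            qc_stats=stats)
        )
    return BinCountMatrix.stack(mats)


def _stage_screen(config: RunConfig, outdir: Path) -> dict[str, Any]:
    q = _quant_settings(config)
    reference = _counts_for(config, "ref", q["n_reference"])
    interval, report = screen_normalization_interval(
        reference, window_bins=q["window_bins"], return_report=True
    )
    report.to_csv(outdir / "screening_report.csv", index=False)
    pd.DataFrame([{
        "chrom": interval.chrom, "start": interval.start, "end": interval.end,
        "stability_cv": interval.stability_score,
        "aneuploidy_freq": interval.aneuploidy_freq,
    }]).to_csv(outdir / "normalization_interval.csv", index=False)
    _READ_CACHE[(id(config), "interval")] = interval
    return {"windows_screened": len(report), "interval": str(interval.chrom)}


def _stage_quantify(config: RunConfig, outdir: Path) -> dict[str, Any]:
    q = _quant_settings(config)
    interval = _READ_CACHE.get((id(config), "interval"))
    if interval is None:
        path = outdir / "normalization_interval.csv"
        if not path.exists():
            raise RuntimeError("screen stage must run before quantify")
        row = pd.read_csv(path).iloc[0]
        interval = NormalizationInterval(
            chrom=str(row["chrom"]), start=int(row["start"]), end=int(row["end"]),
            stability_score=float(row["stability_cv"]),
            aneuploidy_freq=float(row["aneuploidy_freq"]),
        )
    counts = _counts_for(config, "sample", q["n_samples"])
    ratios = compute_mtdna_ratio(counts, interval, scale=config.scale)
    frame = ratios_to_frame(ratios)
    qc_frame = pd.DataFrame([s.as_dict() for s in counts.qc_stats])
    pd.concat([frame, qc_frame], axis=1).to_csv(outdir / "ratios.csv", index=False)
    return {"samples": len(ratios)}


def _stage_qpcr(config: RunConfig, outdir: Path) -> dict[str, Any]:
    plates = read_plates_csv(outdir / "qpcr_plates.csv")
    results = [compute_qpcr_ratio(p) for p in plates]
    results_to_frame(results).to_csv(outdir / "qpcr_ratios.csv", index=False)
    return {"plates": len(results)}


def _stage_concordance(config: RunConfig, outdir: Path) -> dict[str, Any]:
    records = read_biopsies_csv(outdir / "biopsies.csv")
    summary = site_summary(records)
    summary.to_csv(outdir / "site_summary.csv", index=False)
    results = pairwise_site_concordance(records)
    pd.DataFrame(
        {
            "site_a": [r.site_pair[0] for r in results],
            "site_b": [r.site_pair[1] for r in results],
            "n_pairs": [r.n_pairs for r in results],
            "rho": [r.rho for r in results],
            "p_value": [r.p_value for r in results],
        }
    ).to_csv(outdir / "concordance.csv", index=False)

    media = pd.read_csv(outdir / "media_pairs.csv")
    mw = mann_whitney_u(media["biopsy_ratio"], media["media_ratio"])
    pd.DataFrame([{
        "n_biopsy": mw.n_a, "n_media": mw.n_b,
        "mean_biopsy": media["biopsy_ratio"].mean(),
        "mean_media": media["media_ratio"].mean(),
        "U": mw.u, "p_value": mw.p_value, "method": mw.method,
    }]).to_csv(outdir / "media_comparison.csv", index=False)
    return {"embryos": len({r.embryo_id for r in records}),
            "media_pairs": int(mw.n_b)}


def _stage_regress(config: RunConfig, outdir: Path) -> dict[str, Any]:
    timelapse = read_timelapse_csv(outdir / "timelapse.csv")
    screen = feature_screen(timelapse)
    screen.matrix.to_csv(outdir / "feature_correlations.csv")

    linear = fit_ratio_model(timelapse, features=DEFAULT_LINEAR_FEATURES)
    linear.to_frame().to_csv(outdir / "linear_model.csv", index=False)
    linear_inter = fit_ratio_model(
        timelapse, features=DEFAULT_LINEAR_FEATURES,
        interactions=DEFAULT_LINEAR_INTERACTIONS,
    )
    linear_inter.to_frame().to_csv(outdir / "linear_model_interactions.csv", index=False)

    transfers = read_transfers_csv(outdir / "transfers.csv")
    endpoint_models = run_endpoint_models(transfers)
    frames = []
    for endpoint in ENDPOINTS:
        if endpoint in endpoint_models.results:
            f = endpoint_models.results[endpoint].to_frame()
            f.insert(0, "endpoint", endpoint)
            frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(outdir / "endpoint_models.csv", index=False)
    inter_frames = []
    for endpoint, model in endpoint_models.interaction_results.items():
        f = model.to_frame()
        f.insert(0, "endpoint", endpoint)
        inter_frames.append(f)
    if inter_frames:
        pd.concat(inter_frames, ignore_index=True).to_csv(
            outdir / "endpoint_models_interactions.csv", index=False
        )
    return {
        "timelapse_n": linear.n_used,
        "transfer_n": len(transfers),
        "selected_features": screen.selected,
        "endpoint_errors": endpoint_models.errors,
        "linear_converged": not linear.degenerate,
        "endpoints_fit": sorted(endpoint_models.results),
    }


def _stage_report(config: RunConfig, outdir: Path) -> dict[str, Any]:
    lines = [f"mitoquant run report (seed={config.seed})", "=" * 40]
    for name, title in (
        ("site_summary.csv", "Within-blastocyst biopsy summary"),
        ("concordance.csv", "Pairwise site concordance (Spearman)"),
        ("media_comparison.csv", "Biopsy vs spent media (Mann-Whitney U)"),
        ("ratios.csv", "NGS mtDNA ratios"),
        ("qpcr_ratios.csv", "qPCR mtDNA ratios"),
        ("linear_model.csv", "Linear model: ratio ~ morphokinetics"),
        ("endpoint_models.csv", "Logistic endpoint models"),
    ):
        path = outdir / name
        if not path.exists():
            continue
        lines.append("")
        lines.append(title)
        lines.append("-" * len(title))
        lines.append(pd.read_csv(path).to_string(index=False, max_rows=60))
    text = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(text)
    return {"report": "report.txt"}


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "screen": _stage_screen,
    "quantify": _stage_quantify,
    "qpcr": _stage_qpcr,
    "concordance": _stage_concordance,
    "regress": _stage_regress,
    "report": _stage_report,
}
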