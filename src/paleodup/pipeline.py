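"""Run orchestration: configuration, stage ordering, logging, reproducibility.

A run is described by a YAML/dict configuration naming the stages to
execute and their parameters; stages run in dependency order, all outputs
carry a provenance header (tool version, config digest, seed), and a rerun
with the same configuration and seed reproduces identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dating, io, kaks, peaks, simcore, survey, synteny
from .errors import ConfigurationError, DataError

logger = logging.getLogger("paleodup")

STAGES = ("simulate", "synteny", "kaks", "peaks", "date_wgd", "date_ltr", "survey")

#: upstream stage each stage may consume outputs from
_DEPS = {
    "simulate": (),
    "synteny": ("simulate",),
    "kaks": ("synteny", "simulate"),
    "peaks": ("kaks",),
    "date_wgd": ("peaks",),
    "date_ltr": (),
    "survey": (),
}

_KNOWN_KEYS = {"seed", "stages", "outdir", "log_level"} | set(STAGES)


@dataclass
class RunConfig:
    """Validated run configuration."""

    seed: int
    stages: list[str]
    params: dict[str, dict] = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ConfigurationError("config must set a seed")
        stages = list(raw.get("stages", []))
        for st in stages:
            if st not in STAGES:
                raise ConfigurationError(f"unknown stage {st!r}; valid: {STAGES}")
        done: set[str] = set()
        for st in stages:
            needs = _DEPS[st]
            if needs and not any(d in done for d in needs):
                # a stage may instead read explicit input paths
                params = raw.get(st) or {}
                has_inputs = any(k.endswith(("_path", "_file")) or k in
                                 ("hits", "cds", "reads", "ltr_fasta", "kaks_table", "blocks")
                                 for k in params)
                if not has_inputs:
                    raise ConfigurationError(
                        f"stage {st!r} requires one of {needs} earlier in the stage "
                        "list, or explicit input paths in its parameters"
                    )
            done.add(st)
        return cls(
            seed=int(raw["seed"]),
            stages=stages,
            params={st: dict(raw.get(st) or {}) for st in stages},
            log_level=str(raw.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(raw)

    def as_dict(self) -> dict:
        out: dict = {"seed": self.seed, "stages": list(self.stages),
                     "log_level": self.log_level}
        out.update({st: self.params.get(st, {}) for st in self.stages})
        return out


def _setup_logging(outdir: Path, level: str) -> None:
    logger.setLevel(level.upper())
    logger.handlers = [h for h in logger.handlers if not isinstance(h, logging.FileHandler)]
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        logger.addHandler(logging.StreamHandler())
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(fh)


def run(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the configured stages into a run directory.

    Returns the run directory path. Every TSV/JSON output carries the tool
    version, a digest of the resolved configuration and the global seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, config.log_level)
    resolved = config.as_dict()
    digest = io.config_digest(resolved)
    with open(outdir / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
    logger.info("run config digest %s seed %d stages %s", digest, config.seed, config.stages)

    state: dict[str, object] = {}
    for stage in config.stages:
        logger.info("stage %s", stage)
        _RUNNERS[stage](config, config.params.get(stage, {}), state, outdir, digest)
    return outdir


# --- stage runners ---------------------------------------------------------


def _stage_simulate(config: RunConfig, params: dict, state: dict, outdir: Path, digest: str):
    sim_keys = {f.name for f in simcore.SimulationConfig.__dataclass_fields__.values()}
    unknown = set(params) - (sim_keys - {"seed"})
    if unknown:
        raise ConfigurationError(f"simulate: unknown parameters {sorted(unknown)}")
    params = dict(params)  # stage runners must not mutate the run config
    wgd = tuple(params.pop("wgd_times", ()))
    cfg = simcore.SimulationConfig(seed=config.seed, wgd_times=wgd, **params)
    genome = simcore.simulate_lineage(cfg)
    state["genome"] = genome
    state["cds"] = dict(genome.cds)
    genes = genome.gene_models()
    state["genes"] = genes
    io.write_fasta(genome.cds, outdir / "cds.fasta")
    io.write_gff3(genes, outdir / "genes.gff3")
    io.write_bed(genes, outdir / "genes.bed")
    truth_rows = [
        {"gene_id": g, "ancestral_id": t.ancestral_id, "event": t.event}
        for g, t in sorted(genome.truth.items())
    ]
    import pandas as pd

    io.write_tsv(pd.DataFrame(truth_rows), outdir / "truth.tsv", config.seed, digest)
    logger.info("simulated %d genes on %d chromosomes", genome.n_genes,
                len(genome.chromosomes))


def _stage_synteny(config: RunConfig, params: dict, state: dict, outdir: Path, digest: str):
    genes_a = state.get("genes")
    if "gff_a" in params:
        genes_a = io.read_gff3(params["gff_a"])
    if genes_a is None:
        raise DataError("synteny: no gene positions (run simulate or give gff_a)")
    genes_b = io.read_gff3(params["gff_b"]) if "gff_b" in params else genes_a
    if "hits" in params:
        hits = io.read_blast_tab(params["hits"])
    elif "genome" in state:
        hits = simcore.homology_hits(state["genome"])
    else:
        raise DataError("synteny: no homology hits provided")
    anchors = synteny.find_anchors(
        genes_a, genes_b, hits,
        top_k=int(params.get("top_k", synteny.DEFAULT_TOP_K)),
        min_score=float(params.get("min_score", 0.0)),
    )
    blocks = synteny.chain_blocks(
        anchors, genes_a, genes_b,
        min_anchors=int(params.get("min_anchors", synteny.DEFAULT_MIN_ANCHORS)),
        max_gap=int(params.get("max_gap", synteny.DEFAULT_MAX_GAP)),
    )
    state["anchors"], state["blocks"] = anchors, blocks
    state["genes_a"], state["genes_b"] = genes_a, genes_b
    io.write_blocks_tsv(blocks, outdir / "blocks.tsv", config.seed, digest)
    io.write_collinearity(blocks, outdir / "blocks.collinearity")
    profile = synteny.syntenic_depth(blocks, genes_a, genes_b)
    import pandas as pd

    depth_rows = [{"gene_id": g, "genome": "a", "depth": d} for g, d in profile.depth_a.items()]
    if profile.depth_b is not profile.depth_a:
        depth_rows += [{"gene_id": g, "genome": "b", "depth": d}
                       for g, d in profile.depth_b.items()]
    io.write_tsv(pd.DataFrame(depth_rows), outdir / "depth.tsv", config.seed, digest)
    logger.info("%d anchors -> %d blocks, depth ratio %s",
                len(anchors), len(blocks), profile.ratio_label)
    state["depth"] = profile


def _stage_kaks(config: RunConfig, params: dict, state: dict, outdir: Path, digest: str):
    cds = state.get("cds")
    if "cds" in params:
        cds = io.read_fasta(params["cds"])
    blocks = state.get("blocks")
    if blocks is None:
        raise DataError("kaks: no blocks (run synteny first)")
    if cds is None:
        raise DataError("kaks: no CDS sequences")
    table = kaks.kaks_table(blocks, cds)
    state["kaks_table"] = table
    io.write_tsv(table, outdir / "kaks.tsv", config.seed, digest)
    n_sat = int(table["saturated"].sum())
    if n_sat:
        logger.warning("%d saturated pairs flagged", n_sat)


def _stage_peaks(config: RunConfig, params: dict, state: dict, outdir: Path, digest: str):
    table = state.get("kaks_table")
    if "kaks_table" in params:
        table = io.read_tsv(params["kaks_table"])
    if table is None:
        raise DataError("peaks: no Ka/Ks table (run kaks first)")
    dist = peaks.block_median_ks(table, state.get("blocks"))
    curve = peaks.kde(dist, bandwidth=params.get("bandwidth", "auto"))
    model = peaks.fit_gaussian_peaks(
        curve, max_components=int(params.get("max_components", 4)),
        criterion=params.get("criterion", "aicc"),
    )
    state["ks_distribution"], state["curve"], state["peak_model"] = dist, curve, model
    import pandas as pd

    io.write_tsv(pd.DataFrame({"ks": curve.grid, "density": curve.density}),
                 outdir / "ks_density.tsv", config.seed, digest)
    io.write_json_report(
        {
            "n_blocks": int(dist.values.size),
            "bandwidth": curve.bandwidth,
            "components": [
                {"weight": w, "mean": mu, "sd": sd} for w, mu, sd in model.components
            ],
            "n_components": model.n_components,
            "fit_rss": model.fit_rss,
            "selection_trace": {str(k): v for k, v in model.selection_trace.items()},
        },
        outdir / "peaks.json", config.seed, digest,
    )
    logger.info("fitted %d Ks peak(s) at %s", model.n_components,
                [round(m, 3) for m in model.means])


def _stage_date_wgd(config: RunConfig, params: dict, state: dict, outdir: Path, digest: str):
    model = state.get("peak_model")
    if model is None:
        raise DataError("date_wgd: no fitted peaks (run peaks first)")
    rate = float(params.get("rate", 4.21e-9))
    dist = state.get("ks_distribution")
    boots = dist.values if (dist is not None and params.get("bootstrap", False)) else None
    ages = [
        dating.date_wgd(mu, rate, bootstrap_values=boots, seed=config.seed)
        for mu in model.means
    ]
    state["wgd_ages"] = ages
    io.write_json_report(
        {
            "rate": rate,
            "ages_ma": [
                {"peak_ks": a.peak_ks, "age_ma": a.age_ma, "ci_ma": a.ci_ma} for a in ages
            ],
        },
        outdir / "wgd_dating.json", config.seed, digest,
    )
    logger.info("WGD ages (Ma): %s", [round(a.age_ma, 1) for a in ages])


def _stage_date_ltr(config: RunConfig, params: dict, state: dict, outdir: Path, digest: str):
    if "ltr_fasta" in params:
        seqs = io.read_fasta(params["ltr_fasta"])
        items = _pair_ltr_fasta(seqs)
    elif "ltr_cohort" in state:
        items = [(e, s5, s3) for e, s5, s3, _ in state["ltr_cohort"].pairs]
    else:
        raise DataError("date_ltr: no LTR sequences (give ltr_fasta)")
    rate = float(params.get("rate", simcore.LTR_RATE))
    dated = dating.date_ltr_cohort(items, r=rate)
    curve, mode = dating.ltr_burst_profile(dated)
    state["ltr_dated"], state["ltr_mode_k"] = dated, mode
    import pandas as pd

    rows = [
        {"element": p.element_id, "lambda": p.lam,
         "K": np.nan if p.K is None else p.K,
         "T_ma": np.nan if p.T_ma is None else p.T_ma,
         "saturated": p.saturated}
        for p in dated
    ]
    io.write_tsv(pd.DataFrame(rows), outdir / "ltr_dating.tsv", config.seed, digest)
    io.write_json_report(
        {"rate": rate, "mode_K": mode, "mode_T_ma": mode / (2 * rate) / 1e6,
         "n_elements": len(dated)},
        outdir / "ltr_burst.json", config.seed, digest,
    )
    logger.info("LTR burst mode K=%.4f (%.1f Ma at r=%.3g)", mode,
                mode / (2 * rate) / 1e6, rate)


def _pair_ltr_fasta(seqs: dict[str, str]) -> list[tuple[str, str, str]]:
    """Pair `<element>_5p` / `<element>_3p` records from one FASTA."""
    elements: dict[str, dict[str, str]] = {}
    for name, seq in seqs.items():
        if name.endswith(("_5p", "_3p")):
            elements.setdefault(name[:-3], {})[name[-2:]] = seq
        else:
            raise DataError(f"LTR record {name!r} lacks the _5p/_3p suffix")
    out = []
    for element, sides in sorted(elements.items()):
        if set(sides) != {"5p", "3p"}:
            raise DataError(f"element {element!r}: need both _5p and _3p sequences")
        out.append((element, sides["5p"], sides["3p"]))
    return out


def _stage_survey(config: RunConfig, params: dict, state: dict, outdir: Path, digest: str):
    if "reads" in params:
        reads = params["reads"]
    else:
        raise DataError("survey: no reads provided (give reads: <path>)")
    hist = survey.count_kmers(reads, k=int(params.get("k", 17)))
    result = survey.estimate_genome_size(hist)
    state["survey"] = result
    import pandas as pd

    io.write_tsv(
        pd.DataFrame(sorted(hist.counts.items()), columns=["depth", "count"]),
        outdir / "kmer_histogram.tsv", config.seed, digest,
    )
    io.write_json_report(
        {"k": hist.k, "peak_depth": result.peak_depth,
         "error_cutoff": result.error_cutoff,
         "genome_size_bp": result.genome_size_bp},
        outdir / "survey.json", config.seed, digest,
    )
    logger.info("genome size %.0f bp (peak depth %d)", result.genome_size_bp,
                result.peak_depth)


_RUNNERS = {
    "simulate": _stage_simulate,
    "synteny": _stage_synteny,
    "kaks": _stage_kaks,
    "peaks": _stage_peaks,
    "date_wgd": _stage_date_wgd,
    "date_ltr": _stage_date_ltr,
    "survey": _stage_survey,
}
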