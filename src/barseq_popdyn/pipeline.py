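"""End-to-end orchestration from a single config.

Runs counting (or count-table loading) -> t0 filtering -> normalization ->
detection/loss tracking -> Pearson correlation -> Bray-Curtis -> ordination
-> PERMANOVA / beta dispersion -> selection classification -> Venn overlap
-> term enrichment, writing every stage's output as TSV and collecting a
machine-readable report with checksums and the recorded seed so reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .barcode_quant import (
    CountTable,
    SampleMeta,
    count_reads,
    filter_t0,
    load_catalog,
    normalize,
)
from .ecology import beta_dispersion, bray_curtis, nmds, pcoa, permanova
from .population_stats import (
    DEFAULT_THRESHOLDS,
    detection_profile,
    loss_windows,
    loss_windows_frame,
    pearson_matrix,
)
from .selection_enrichment import (
    AnnotationMap,
    calls_frame,
    classify_selection,
    compare_conditions,
    enrichment_frame,
    hypergeometric_enrichment,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""


@dataclass
class RunConfig:
    outdir: Path
    seed: int
    t0_sample: str
    # inputs: either FASTQ per sample (+catalog) or a pre-made count table
    counts: Path | None = None
    sample_sheet: Path | None = None
    fastq: dict[str, Path] = field(default_factory=dict)
    catalog: Path | None = None
    flank: str = ""
    barcode_length: int = 20
    annotation: Path | None = None
    # thresholds
    t0_threshold: int = 10
    detection_threshold: int = 10
    loss_thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS
    loss_threshold: int = 10
    depletion_fraction: float = 0.5
    enrichment_fold: float = 2.0
    pseudocount: int = 10
    # ecology
    k: int = 2
    n_restarts: int = 20
    n_permutations: int = 999
    permanova_terms: list[dict[str, Any]] = field(default_factory=list)
    dispersion_group: str = "condition"
    # selection
    selection_windows: list[dict[str, Any]] = field(default_factory=list)
    venn_statuses: tuple[str, ...] = ("lost", "depleted")

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        for name in ("t0_threshold", "detection_threshold", "loss_threshold",
                     "pseudocount", "n_permutations", "k", "n_restarts"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.counts is None and not self.fastq:
            raise ValueError("config needs either counts or fastq inputs")
        if self.fastq and (self.catalog is None or not self.flank):
            raise ValueError("fastq input needs a catalog and a flank")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("counts", "sample_sheet", "catalog", "annotation"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        if "fastq" in raw and raw["fastq"]:
            raw["fastq"] = {k: Path(v) for k, v in raw["fastq"].items()}
        for key in ("loss_thresholds", "venn_statuses"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        # outdir is a location, not an analysis parameter: identical configs
        # run into different directories must stamp identical hashes
        payload = json.dumps(
            {k: str(v) for k, v in sorted(self.__dict__.items())
             if k != "outdir"},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    version: str
    config_hash: str
    seed: int
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def record(self, stage: str, status: str, paths: list[Path]) -> None:
        self.stages[stage] = {
            "status": status,
            "outputs": [str(p) for p in paths],
            "checksums": {p.name: _sha256(p) for p in paths if p.exists()},
        }

    def all_green(self) -> bool:
        return all(s["status"] in ("ok", "skipped(input)")
                   for s in self.stages.values())

    def to_json(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(frame: pd.DataFrame, path: Path, comment: str, index: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {comment}\n")
        frame.to_csv(fh, sep="\t", index=index)


def run_all(config: RunConfig) -> RunReport:
    """Execute every enabled stage; abort on the first failure, naming it."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    report = RunReport(version=__version__, config_hash=chash, seed=config.seed)
    stamp = f"barseq-popdyn v{__version__} config={chash}"

    def stage(name: str):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:
                report.record(name, f"failed: {exc}", [])
                report.to_json(outdir / "report.json")
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            return result
        return deco

    # -- counting ------------------------------------------------------
    if config.fastq:
        @stage("count")
        def table() -> CountTable:
            catalog = load_catalog(config.catalog)
            sheet = pd.read_csv(
                config.sample_sheet, sep="\t", comment="#", index_col="sample_id"
            )
            tables = []
            for sid, path in config.fastq.items():
                row = sheet.loc[sid]
                meta = SampleMeta(sid, row["condition"], row["vessel"],
                                  float(row["time_h"]))
                tables.append(count_reads(path, catalog, meta, config.flank,
                                          config.barcode_length))
            merged = tables[0]
            for t in tables[1:]:
                merged = merged.concat(t)
            return merged
        counts_path = outdir / "counts_raw.tsv"
        samples_path = outdir / "samples.tsv"
        table.to_tsv(counts_path, samples_path,
                     header_comment=f"{stamp} units=reads")
        report.record("count", "ok", [counts_path, samples_path])
    else:
        @stage("count")
        def table() -> CountTable:
            return CountTable.from_tsv(config.counts, config.sample_sheet)
        report.record("count", "skipped(input)", [])

    # -- t0 filter -----------------------------------------------------
    @stage("filter_t0")
    def filtered() -> CountTable:
        return filter_t0(table, config.t0_sample, config.t0_threshold)
    p = outdir / "counts_filtered.tsv"
    ps = outdir / "samples_filtered.tsv"
    filtered.to_tsv(p, ps, header_comment=f"{stamp} units=reads")
    report.record("filter_t0", "ok", [p, ps])

    # -- normalize -----------------------------------------------------
    @stage("normalize")
    def abundances():
        return normalize(filtered, config.pseudocount)
    p = outdir / "abundance.tsv"
    abundances.to_tsv(p, outdir / "samples_filtered.tsv",
                      header_comment=f"{stamp} units=relative_abundance")
    report.record("normalize", "ok", [p])

    # -- detection + loss windows --------------------------------------
    @stage("diversity")
    def diversity_frames():
        det_rows = []
        for sid in filtered.sample_ids:
            prof = detection_profile(filtered, sid, config.detection_threshold)
            det_rows.append({"sample_id": sid,
                             "threshold": prof.threshold,
                             "n_detected": prof.n_detected,
                             "n_not_detected": prof.n_not_detected})
        windows_all = []
        for cond in pd.unique(filtered.meta["condition"]):
            if (filtered.meta["condition"] == cond).sum() >= 2:
                wins, _ = loss_windows(filtered, cond, config.loss_thresholds)
                windows_all.extend(wins)
        return pd.DataFrame(det_rows), loss_windows_frame(windows_all)
    det_frame, loss_frame = diversity_frames
    p1, p2 = outdir / "detection.tsv", outdir / "loss_windows.tsv"
    _write(det_frame, p1, f"{stamp} units=genes", index=False)
    _write(loss_frame, p2, f"{stamp} units=genes", index=False)
    report.record("diversity", "ok", [p1, p2])

    # -- Pearson -------------------------------------------------------
    @stage("pearson")
    def corr():
        import warnings as _w
        with _w.catch_warnings(record=True) as caught:
            _w.simplefilter("always")
            result = pearson_matrix(filtered)
        for w in caught:
            report.warnings.append(str(w.message))
        return result
    p = outdir / "pearson.tsv"
    _write(corr.to_dataframe(), p, f"{stamp} units=pearson_r")
    report.record("pearson", "ok", [p])

    # -- Bray-Curtis + ordination --------------------------------------
    @stage("bray_curtis")
    def dm():
        return bray_curtis(abundances)
    p = outdir / "bray_curtis.tsv"
    _write(dm.to_dataframe(), p, f"{stamp} units=dissimilarity")
    report.record("bray_curtis", "ok", [p])

    @stage("ordination")
    def ords():
        nm = nmds(dm, k=config.k, n_restarts=config.n_restarts,
                  seed=config.seed)
        if not nm.converged:
            report.warnings.append("NMDS did not converge in max_iter")
        pc = pcoa(dm, k=min(config.k, dm.n - 1))
        return nm, pc
    nm, pc = ords
    p1, p2 = outdir / "nmds.tsv", outdir / "pcoa.tsv"
    _write(nm.to_dataframe(), p1,
           f"{stamp} units=nmds_axes stress={nm.stress:.6f} seed={config.seed}")
    _write(pc.to_dataframe(), p2, f"{stamp} units=pcoa_axes")
    (outdir / "nmds_meta.json").write_text(json.dumps(
        {"stress": nm.stress, "seed": config.seed,
         "n_restarts": config.n_restarts, "converged": nm.converged}))
    report.record("ordination", "ok", [p1, p2, outdir / "nmds_meta.json"])

    # -- PERMANOVA + dispersion ----------------------------------------
    @stage("permanova")
    def perm_frame():
        rows = []
        meta = filtered.meta
        for i, spec in enumerate(config.permanova_terms):
            term = spec["term"]
            labels = meta[term] if term in meta.columns else meta["time_h"]
            strata = meta[spec["strata"]] if spec.get("strata") else None
            res = permanova(dm, labels.to_numpy(),
                            n_permutations=config.n_permutations,
                            strata=None if strata is None else strata.to_numpy(),
                            seed=config.seed + i, term=term)
            rows.append({"term": res.term, "pseudo_F": res.pseudo_F,
                         "R2": res.R2, "p_value": res.p_value,
                         "n_permutations": res.n_permutations,
                         "strata": spec.get("strata") or ""})
        return pd.DataFrame(rows)
    if config.permanova_terms:
        p = outdir / "permanova.tsv"
        _write(perm_frame, p, f"{stamp} units=pseudo_F seed={config.seed}",
               index=False)
        report.record("permanova", "ok", [p])

    @stage("dispersion")
    def disp():
        result = beta_dispersion(
            dm, filtered.meta[config.dispersion_group].to_numpy(),
            n_permutations=config.n_permutations, seed=config.seed)
        if result.excluded_groups:
            report.warnings.append(
                f"dispersion: singleton groups excluded {result.excluded_groups}")
        return result
    p = outdir / "dispersion.tsv"
    _write(pd.DataFrame({"sample_id": disp.sample_ids, "group": disp.groups,
                         "distance_to_centroid": disp.distances}),
           p, f"{stamp} units=distance anova_F={disp.anova_F:.4f} "
              f"anova_p={disp.anova_p:.4g} perm_p={disp.permutation_p:.4g}",
           index=False)
    report.record("dispersion", "ok", [p])

    # -- selection / venn / enrichment ---------------------------------
    calls_by_cond = {}
    if config.selection_windows:
        @stage("selection")
        def selection_frames():
            frames = []
            for spec in config.selection_windows:
                calls = classify_selection(
                    filtered, abundances, spec["condition"],
                    float(spec["t_from"]), float(spec["t_to"]),
                    config.loss_threshold, config.depletion_fraction,
                    config.enrichment_fold)
                calls_by_cond[spec["condition"]] = calls
                frames.append(calls_frame(calls))
            return pd.concat(frames, ignore_index=True)
        p = outdir / "selection_calls.tsv"
        _write(selection_frames, p, f"{stamp} units=calls", index=False)
        report.record("selection", "ok", [p])

    if len(calls_by_cond) >= 2:
        @stage("venn")
        def venn_frame():
            regions = compare_conditions(calls_by_cond, config.venn_statuses)
            return pd.DataFrame(
                {"region": ["&".join(r.conditions) for r in regions],
                 "n": [r.n for r in regions],
                 "genes": [",".join(sorted(r.genes)) for r in regions]})
        p = outdir / "venn.tsv"
        _write(venn_frame, p, f"{stamp} units=genes", index=False)
        report.record("venn", "ok", [p])

    if config.annotation is not None and calls_by_cond:
        @stage("enrichment")
        def enr_frames():
            ann = AnnotationMap.from_tsv(config.annotation,
                                         background=filtered.genes)
            frames = []
            for cond, calls in calls_by_cond.items():
                hit = [c.gene for c in calls if c.status in config.venn_statuses]
                if not hit:
                    continue
                frame = enrichment_frame(hypergeometric_enrichment(hit, ann))
                frame.insert(0, "condition", cond)
                frames.append(frame)
            return (pd.concat(frames, ignore_index=True)
                    if frames else pd.DataFrame())
        p = outdir / "enrichment.tsv"
        _write(enr_frames, p, f"{stamp} units=fold_enrichment", index=False)
        report.record("enrichment", "ok", [p])

    report.to_json(outdir / "report.json")
    return report
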