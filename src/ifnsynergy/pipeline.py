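"""End-to-end orchestration of the analysis stages over plain-text files.

Stages run in order: simulate (optional) -> classify-peaks -> inducible ->
link -> isg -> induced fractions -> enhance.  Every stage reads and writes
TSV/BED/FASTA in one output directory, and a run manifest records the config
snapshot, the seed, SHA-256 digests of all inputs and outputs, and the
headline summary counts.  With a fixed config and seed the manifest is
byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ifnsynergy.dynamics import cluster_kinetics, find_inducible, scale_rows
from ifnsynergy.enhancement import (
    build_enhancement_records,
    compare_quartiles,
    es_by_promoter_motif,
    quartile_partition,
)
from ifnsynergy.errors import PipelineError
from ifnsynergy.expression import call_isgs, filter_expressed, max_fold_change, normalize
from ifnsynergy.io import (
    AnalysisConfig,
    condition_metadata,
    read_bed,
    read_fasta,
    read_matrix,
    read_tss_table,
)
from ifnsynergy.linking import link_peaks, link_summary, unique_gene_table
from ifnsynergy.motifs import classify_peaks
from ifnsynergy.synthetic import SimulationParams, simulate_all, write_dataset

logger = logging.getLogger("ifnsynergy.pipeline")

INPUT_FILES = (
    "genome.fa",
    "peaks.bed",
    "chip_signal.tsv",
    "counts.tsv",
    "gene_lengths.tsv",
    "tss.tsv",
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def chip_groups(columns) -> dict:
    """Partition ChIP signal columns by metadata: basal, and per-dose stimulated."""
    meta = condition_metadata(columns)
    basal = [c for c in columns if meta[c] is not None and meta[c].time == 0]
    doses = sorted({m.dose for m in meta.values() if m is not None and m.time > 0})
    per_dose = {
        d: [c for c in columns if meta[c] is not None and meta[c].time > 0 and meta[c].dose == d]
        for d in doses
    }
    return {"basal": basal, "doses": doses, "per_dose": per_dose, "meta": meta}


def rna_groups(columns) -> dict[str, list[str]]:
    """Map RNA sample columns to conditions by the column-name convention.

    ``beta`` columns are split into low/high by dose (min vs max); ``unstim``,
    ``gamma`` and ``mixed`` map directly.  Unparseable columns are ignored.
    """
    meta = condition_metadata(columns)
    groups: dict[str, list[str]] = {}
    beta_doses = sorted({m.dose for m in meta.values() if m is not None and m.stimulus == "beta"})
    for c in columns:
        m = meta[c]
        if m is None:
            continue
        if m.stimulus == "unstim" or m.time == 0:
            groups.setdefault("unstim", []).append(c)
        elif m.stimulus == "beta":
            label = "beta_high" if m.dose == beta_doses[-1] else "beta_low"
            if len(beta_doses) == 1:
                label = "beta_high"
            groups.setdefault(label, []).append(c)
        elif m.stimulus in ("gamma", "mixed"):
            groups.setdefault(m.stimulus, []).append(c)
    return groups


@dataclass
class RunManifest:
    """Snapshot of one pipeline run: config, inputs, outputs, summary counts."""

    config: dict
    seed: int
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def run_all(
    config: AnalysisConfig,
    outdir: str | Path,
    simulate: bool = False,
    sim_params: SimulationParams | None = None,
) -> RunManifest:
    """Run every stage in order and write the manifest.

    With ``simulate=True`` the synthetic generator first writes the input
    files; otherwise they must already exist in ``outdir`` (a missing file
    aborts, naming the file).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)

    if simulate:
        params = sim_params or SimulationParams(seed=config.seed)
        logger.info("stage simulate: n_peaks=%d n_genes=%d", params.n_peaks, params.n_genes)
        ds = simulate_all(params)
        write_dataset(ds, outdir)
    for name in INPUT_FILES:
        path = outdir / name
        if not path.exists():
            raise PipelineError(f"stage inputs: missing input file {path}")
        manifest.inputs[name] = _sha256(path)

    # --- classify
    try:
        peaks = read_bed(outdir / "peaks.bed")
        genome = read_fasta(outdir / "genome.fa")
        categories = classify_peaks(peaks, genome)
        categories.to_csv(outdir / "categories.tsv", sep="\t")
    except Exception as exc:
        raise PipelineError(f"stage classify-peaks failed on peaks.bed: {exc}") from exc

    # --- inducible + kinetics
    try:
        signal = read_matrix(outdir / "chip_signal.tsv")
        inducible = find_inducible(
            signal,
            fold=config.induction_fold,
            min_timepoints=config.min_timepoints,
            exclude_cols=config.exclude_columns,
            pseudocount=config.signal_pseudocount,
        )
        groups = chip_groups(signal.columns)
        high_dose = groups["doses"][-1]
        meta = groups["meta"]
        by_time: dict[float, list[str]] = {}
        for c in groups["per_dose"][high_dose]:
            by_time.setdefault(meta[c].time, []).append(c)
        profile = pd.DataFrame(
            {t: signal[cols].mean(axis=1) for t, cols in sorted(by_time.items())}
        )
        scaled = scale_rows(profile.loc[inducible], pseudocount=config.signal_pseudocount)
        clusters = cluster_kinetics(
            scaled,
            times=sorted(by_time),
            k_candidates=config.k_candidates,
            seed=config.seed,
        )
        out = pd.DataFrame({"inducible": inducible})
        out["cluster"] = clusters.labels.reindex(out.index)
        out.to_csv(outdir / "inducible.tsv", sep="\t")
    except Exception as exc:
        raise PipelineError(f"stage inducible failed on chip_signal.tsv: {exc}") from exc

    # --- expression normalization (shared by link/isg/enhance)
    try:
        counts = read_matrix(outdir / "counts.tsv")
        lengths = read_matrix(outdir / "gene_lengths.tsv")["length"]
        norm = normalize(counts, lengths, method="tmm")
        expressed = filter_expressed(norm, config.cpm_filter)
        rgroups = rna_groups(counts.columns)
    except Exception as exc:
        raise PipelineError(f"stage expression failed on counts.tsv: {exc}") from exc

    # --- link
    try:
        tss = read_tss_table(outdir / "tss.tsv")
        linkable = [
            p
            for p in peaks
            if inducible.get(p.name, False) and categories.loc[p.name, "category"] != "NO_MOTIF"
        ]
        links = link_peaks(
            linkable,
            tss,
            set(expressed),
            categories=categories["category"],
            promoter_window=config.promoter_window,
        )
        gene_table = unique_gene_table(links)
        links.to_csv(outdir / "links.tsv", sep="\t", index=False)
        gene_table.to_csv(outdir / "gene_table.tsv", sep="\t")
        link_summary(gene_table).to_csv(outdir / "link_summary.tsv", sep="\t")
    except Exception as exc:
        raise PipelineError(f"stage link failed on tss.tsv: {exc}") from exc

    # --- isg
    try:
        stim_groups = {"beta_high": rgroups["beta_high"]}
        isg_table = call_isgs(
            norm.rpkm.loc[expressed],
            stim_groups,
            rgroups["unstim"],
            fdr=config.isg_fdr,
            fold=config.isg_fold,
            pseudocount=config.rpkm_pseudocount,
        )
        isg_table.to_csv(outdir / "isg.tsv", sep="\t")
    except Exception as exc:
        raise PipelineError(f"stage isg failed on counts.tsv: {exc}") from exc

    # --- induced fractions by linked-peak category
    try:
        maxfc = max_fold_change(
            norm.rpkm.loc[expressed],
            stim_groups,
            rgroups["unstim"],
            pseudocount=config.rpkm_pseudocount,
        )
        frac_rows = []
        for cat, grp in gene_table.groupby("category"):
            genes = [g for g in grp.index if g in maxfc.index]
            if not genes:
                continue
            induced = int((maxfc.loc[genes] > config.isg_fold).sum())
            frac_rows.append(
                {
                    "category": cat,
                    "n_genes": len(genes),
                    "n_induced": induced,
                    "fraction": induced / len(genes),
                }
            )
        fractions = pd.DataFrame(frac_rows).set_index("category")
        fractions.to_csv(outdir / "induced_fractions.tsv", sep="\t")
    except Exception as exc:
        raise PipelineError(f"stage induced-fraction failed: {exc}") from exc

    # --- enhancement
    enhancement_summary: dict = {}
    if {"mixed", "gamma", "beta_low"}.issubset(rgroups):
        try:
            isg_genes = isg_table.index[isg_table["isg"]]
            records = build_enhancement_records(
                norm.rpkm,
                mixed_cols=rgroups["mixed"],
                beta_cols=rgroups["beta_low"],
                gamma_cols=rgroups["gamma"],
                basal_cols=rgroups["unstim"],
                genes=isg_genes,
                gene_table=gene_table,
                genome=genome,
                tss_table=tss,
                pseudocount=config.rpkm_pseudocount,
                gc_window=config.gc_window,
            )
            records.to_csv(outdir / "enhancement.tsv", sep="\t")
            _, thresholds = quartile_partition(records["es"])
            comp = compare_quartiles(
                records[records["quartile"] == "TOP"],
                records[records["quartile"] == "BOTTOM"],
            )
            motif_cmp = es_by_promoter_motif(records)
            enhancement_summary = {
                "n_isgs": int(len(records)),
                "quartile_size": int((records["quartile"] == "TOP").sum()),
                "es_threshold_top": thresholds["top"],
                "es_threshold_bottom": thresholds["bottom"],
                "promoter_peak_pct_top": comp.promoter_fractions[0],
                "promoter_peak_pct_bottom": comp.promoter_fractions[1],
                "basal_p": comp.basal_test.p_value if comp.basal_test else None,
                "gc_p": comp.gc_test.p_value if comp.gc_test else None,
                "promoter_fisher_p": comp.promoter_fisher.p_value,
                "es_both_vs_isre_p": motif_cmp.test.p_value if motif_cmp.test else None,
            }
            Path(outdir / "enhancement_report.json").write_text(
                json.dumps(enhancement_summary, indent=2, sort_keys=True) + "\n"
            )
        except Exception as exc:
            raise PipelineError(f"stage enhance failed: {exc}") from exc

    inducible_cats = categories.loc[inducible[inducible].index, "category"]
    cat_counts = inducible_cats.value_counts().to_dict()
    manifest.summary = {
        "n_peaks": int(len(peaks)),
        "n_inducible": int(inducible.sum()),
        "category_counts_all": categories["category"].value_counts().to_dict(),
        "category_counts_inducible": {k: int(v) for k, v in sorted(cat_counts.items())},
        "chosen_k": int(clusters.chosen_k),
        "cluster_sizes": {
            int(k): int(v) for k, v in clusters.labels.value_counts().sort_index().items()
        },
        "n_expressed": int(len(expressed)),
        "n_linked_genes": int(len(gene_table)),
        "n_promoter_linked": int(gene_table["promoter"].sum()),
        "n_distal_linked": int((~gene_table["promoter"]).sum()),
        "n_isgs": int(isg_table["isg"].sum()),
        "enhancement": enhancement_summary,
    }

    for path in sorted(outdir.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest.outputs[path.name] = _sha256(path)
    manifest.write(outdir / "manifest.json")

    # internal consistency: inducible category counts sum to the inducible total
    assert sum(cat_counts.values()) == int(inducible.sum())
    return manifest
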