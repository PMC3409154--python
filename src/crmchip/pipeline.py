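"""End-to-end orchestration: configuration, staged runs, provenance, reports.

A run is fully determined by its configuration and seed: it simulates
(or loads) an alignment, scans and selects candidate motif sites,
designs amplicon windows and control regions, simulates and analyses a
ChIP extract pair over the candidate amplicons, simulates and analyses
an expression contrast with a fold-scanning FDR curve, and writes every
table with a provenance manifest. Re-running an identical configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from crmchip import __version__
from crmchip.errors import ConfigError
from crmchip.expression import fold_scan_fdr, fold_table, foldscan_table, signed_fold
from crmchip.motifs import (
    amplicons_to_table,
    annotate_conservation,
    controls_to_table,
    design_amplicon_window,
    scan_reference_motifs,
    select_candidate_sites,
    select_control_regions,
    sites_to_bed,
)
from crmchip.occupancy import analyze_plates, results_table
from crmchip.simulate import (
    AlnSimConfig,
    ChipSimConfig,
    ExprSimConfig,
    demo_alignment_config,
    simulate_alignment,
    simulate_chip_pair,
    simulate_expression,
)

logger = logging.getLogger("crmchip.pipeline")

RESULT_FILES = (
    "sites.bed",
    "amplicons.tsv",
    "controls.tsv",
    "occupancy.tsv",
    "expression_folds.tsv",
    "foldscan.tsv",
)


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one pipeline run (all stages)."""

    seed: int = 0
    out_dir: str = "run"
    motif: str = "TAATCY"
    min_species: int = 6
    amplicon_target_len: int = 110
    control_exclusion: int = 1000
    n_controls: int = 2
    fold_cutoffs: tuple[float, ...] = (1.2, 1.4, 2.0)
    alignment: AlnSimConfig | None = None
    chip: ChipSimConfig | None = None
    expression: ExprSimConfig | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "alignment" in kwargs and kwargs["alignment"] is not None:
            aln = dict(kwargs["alignment"])
            if "species" in aln:
                aln["species"] = tuple(aln["species"])
            if "planted_sites" in aln:
                aln["planted_sites"] = tuple(
                    (int(pos), tuple(subset)) for pos, subset in aln["planted_sites"]
                )
            kwargs["alignment"] = AlnSimConfig(**aln)
        if "chip" in kwargs and kwargs["chip"] is not None:
            chip = dict(kwargs["chip"])
            if "k_interval" in chip:
                chip["k_interval"] = tuple(chip["k_interval"])
            kwargs["chip"] = ChipSimConfig(**chip)
        if "expression" in kwargs and kwargs["expression"] is not None:
            expr = dict(kwargs["expression"])
            if "planted_folds" in expr:
                expr["planted_folds"] = {int(i): float(f) for i, f in expr["planted_folds"].items()}
            if "fold_range" in expr:
                expr["fold_range"] = tuple(expr["fold_range"])
            kwargs["expression"] = ExprSimConfig(**expr)
        if "fold_cutoffs" in kwargs:
            kwargs["fold_cutoffs"] = tuple(float(c) for c in kwargs["fold_cutoffs"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = repr(self).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def default_run_config(seed: int = 0, out_dir: str = "run") -> RunConfig:
    """Demo configuration exercising every stage on synthetic inputs."""
    return RunConfig(
        seed=seed,
        out_dir=out_dir,
        alignment=demo_alignment_config(seed=seed),
        chip=ChipSimConfig(seed=seed + 1),
        expression=ExprSimConfig(
            n_genes=400, regulated_fraction=0.05, seed=seed + 2
        ),
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write the result tables plus a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "outputs": {},
    }

    try:
        # --- motif stage -------------------------------------------------
        aln_cfg = config.alignment or demo_alignment_config(seed=config.seed)
        logger.info("stage alignment: simulating %d-species block", len(aln_cfg.species))
        block, truth_sites = simulate_alignment(aln_cfg)
        sites = annotate_conservation(
            block, scan_reference_motifs(block, config.motif), config.motif
        )
        candidates = select_candidate_sites(sites, config.min_species)
        logger.info(
            "stage motifs: %d sites, %d candidates at min_species=%d",
            len(sites), len(candidates), config.min_species,
        )
        windows = [
            design_amplicon_window(
                s, block.ref_length, config.amplicon_target_len, ref_start=block.ref_start
            )
            for s in candidates
        ]
        controls = select_control_regions(
            block.ref_length,
            sites,
            region_len=config.amplicon_target_len,
            exclusion=config.control_exclusion,
            n=config.n_controls,
            ref_start=block.ref_start,
            chrom=block.ref_chrom,
        )
        _write(out, "sites.bed", sites_to_bed(sites), manifest, header=False)
        _write(out, "amplicons.tsv", amplicons_to_table(windows), manifest)
        _write(out, "controls.tsv", controls_to_table(controls), manifest)
        truth_sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)

        # --- occupancy stage ---------------------------------------------
        chip_cfg = config.chip or ChipSimConfig(seed=config.seed + 1)
        amplicons = {
            f"amp_{w.start}_{w.end}": chip_cfg.true_occupancy for w in windows
        } or {"amp1": chip_cfg.true_occupancy}
        plate, meta = simulate_chip_pair(chip_cfg, amplicons)
        occ = analyze_plates([plate])
        for r in occ:
            if not (0.5 <= r.k <= 2.0):
                logger.warning("amplicon %s: k=%.3g outside [0.5, 2]", r.amplicon_id, r.k)
        logger.info("stage occupancy: %d amplicons, k ~ %.3g", len(occ), occ[0].k if occ else float("nan"))
        plate.to_csv(out / "plate.csv", index=False)
        _write(out, "occupancy.tsv", results_table(occ), manifest)
        manifest["chip_meta"] = {k: v for k, v in meta.items() if k != "true_occupancy"}

        # --- expression stage --------------------------------------------
        expr_cfg = config.expression or ExprSimConfig(seed=config.seed + 2)
        matrix, truth_expr = simulate_expression(expr_cfg)
        wt_cols = [c for c in matrix.columns if c.startswith("WT_")]
        mut_cols = [c for c in matrix.columns if c.startswith("MUT_")]
        records = [
            signed_fold(row[wt_cols], row[mut_cols], probe_id=str(pid))
            for pid, row in matrix.iterrows()
        ]
        scan = fold_scan_fdr(matrix, wt_cols, mut_cols, config.fold_cutoffs)
        logger.info("stage expression: %d probes, %d fold cutoffs", len(records), len(scan))
        _write(out, "expression_folds.tsv", fold_table(records), manifest)
        _write(out, "foldscan.tsv", foldscan_table(scan), manifest)
        truth_expr.to_csv(out / "truth_expression.tsv", sep="\t")

        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def _write(out: Path, name: str, df: pd.DataFrame, manifest: dict, header: bool = True) -> None:
    path = out / name
    df.to_csv(path, sep="\t", index=False, header=header)
    manifest["outputs"][name] = {"rows": int(len(df)), "columns": list(df.columns)}


def render_report(run_dir) -> str:
    """Human-readable markdown summary of a completed run."""
    run_dir = Path(run_dir)
    lines = ["# Pipeline run report", ""]
    warnings_ = []

    occ_path = run_dir / "occupancy.tsv"
    if occ_path.exists():
        occ = pd.read_csv(occ_path, sep="\t")
        lines.append("## Occupancy per amplicon")
        lines.append("")
        if len(occ) == 0:
            lines.append("No amplicons measured.")
        else:
            for _, row in occ.iterrows():
                lines.append(
                    f"- {row['amplicon_id']} ({row['antibody']}, pair {row['pair_id']}): "
                    f"k={row['k']:.3f}, occupancy {row['percent_occupancy']:.2f}% "
                    f"± {row['percent_sd']:.2f}%, p={row['p_value']:.3g}, code {row['code']}"
                )
        lines.append("")
        lines.append(
            "Code legend: **** p<0.0001, *** p<0.01, ** p<0.05, * p<0.1, "
            "+- p<0.3, ne no evidence, nd not detected."
        )
        lines.append("")
    else:
        warnings_.append("occupancy.tsv missing")

    scan_path = run_dir / "foldscan.tsv"
    if scan_path.exists():
        scan = pd.read_csv(scan_path, sep="\t")
        lines.append("## Fold-scanning FDR")
        lines.append("")
        lines.append("| cutoff | observed | null (mean) | FDR |")
        lines.append("|---|---|---|---|")
        for _, row in scan.iterrows():
            fdr = f"{row['fdr']:.3f}" if pd.notna(row["fdr"]) else "NA"
            lines.append(
                f"| {row['cutoff']:g} | {int(row['n_observed'])} | {row['n_null']:.2f} | {fdr} |"
            )
        lines.append("")
    else:
        warnings_.append("foldscan.tsv missing")

    if warnings_:
        lines.append("## Warnings")
        lines.extend(f"- {w}" for w in warnings_)
        lines.append("")
    return "\n".join(lines)
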