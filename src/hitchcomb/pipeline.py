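"""End-to-end orchestration: QC -> iHS scan -> mixed-model WGA -> combined
test, with a key=value config file, per-stage TSV outputs and a JSON run
manifest (resolved config, master seed, input digests, stage counts)."""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .combine import combine_scan
from .datatypes import GenotypeTable
from .ihs import scan_panel
from .io_qc import (
    QcOptions,
    qc_filter,
    read_ancestral,
    read_pedigree,
    read_phased_vcf,
    read_phenotypes,
    read_plink_text,
)
from .wga import association_scan, inflation_factor, load_grm, qq_table

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Aggregated configuration problems; str() lists all of them."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


_DEFAULTS = {
    "n_perm": 1000,
    "cutoff": 0.05,
    "min_family": 5,
    "q_threshold": 0.10,
    "alpha_bonf": 2.5e-5,
    "seed": 0,
    "model": "MIXStrat",
    "fdr_method": "tail_area",
    "maf_min": 0.05,
    "snp_missing_max": 0.10,
    "indiv_callrate_min": 0.90,
}
_INT_KEYS = {"n_perm", "min_family", "seed"}
_FLOAT_KEYS = {"cutoff", "q_threshold", "alpha_bonf", "maf_min",
               "snp_missing_max", "indiv_callrate_min"}
_PATH_KEYS = {"vcf", "ped", "map", "phenotypes", "pedigree", "ancestral",
              "grm_file"}
_CHOICE_KEYS = {"model": {"MIX", "MIXStrat"}, "fdr_method": {"tail_area", "bh"}}


def validate_config(path_or_dict) -> dict:
    """Parse and validate a key=value config; fill defaults, reject unknown
    keys.  All problems are collected and reported at once."""
    raw = {}
    if isinstance(path_or_dict, dict):
        raw = {str(k): str(v) for k, v in path_or_dict.items()}
    else:
        for ln, line in enumerate(Path(path_or_dict).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError([f"line {ln}: expected key = value"])
            k, v = line.split("=", 1)
            raw[k.strip()] = v.strip()

    errors = []
    cfg = dict(_DEFAULTS)
    known = set(_DEFAULTS) | _PATH_KEYS
    for k, v in raw.items():
        if k not in known:
            errors.append(f"unknown config key {k!r}")
            continue
        if k in _INT_KEYS:
            try:
                cfg[k] = int(v)
            except ValueError:
                errors.append(f"{k}: expected integer, got {v!r}")
        elif k in _FLOAT_KEYS:
            try:
                cfg[k] = float(v)
            except ValueError:
                errors.append(f"{k}: expected number, got {v!r}")
        elif k in _CHOICE_KEYS:
            if v not in _CHOICE_KEYS[k]:
                errors.append(f"{k}: must be one of {sorted(_CHOICE_KEYS[k])}")
            else:
                cfg[k] = v
        else:
            cfg[k] = v
    for k in _PATH_KEYS & set(cfg):
        if not Path(cfg[k]).exists():
            errors.append(f"{k}: file not found: {cfg[k]}")
    if errors:
        raise ConfigError(errors)
    return cfg


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config, out_dir) -> Path:
    """Run all stages and write stage TSVs, the combined table, QQ tables
    and the run manifest into ``out_dir``.  A stage failure halts the run
    with partial outputs preserved."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = _dt.datetime.now().isoformat(timespec="seconds")

    errors = []
    if "vcf" not in cfg:
        errors.append("a phased VCF input is required (key 'vcf')")
    if "phenotypes" not in cfg:
        errors.append("a phenotype TSV is required (key 'phenotypes')")
    if "pedigree" not in cfg:
        errors.append("a pedigree TSV is required (key 'pedigree')")
    if errors:
        raise ConfigError(errors)

    manifest = {
        "tool": "hitchcomb",
        "version": __version__,
        "subcommand": "pipeline",
        "config": {k: cfg[k] for k in sorted(cfg)},
        "seed": cfg["seed"],
        "inputs": {k: _digest(cfg[k]) for k in _PATH_KEYS & set(cfg)},
        "started": started,
        "counts": {},
    }

    stage = "qc"
    try:
        panel = read_phased_vcf(cfg["vcf"])
        if "ped" in cfg and "map" in cfg:
            gt = read_plink_text(cfg["ped"], cfg["map"])
        else:
            codes = (panel.alleles[0::2] + panel.alleles[1::2]).astype(np.int8)
            gt = GenotypeTable(codes, panel.variants.copy(), panel.individual_ids)
        opts = QcOptions(cfg["maf_min"], cfg["snp_missing_max"],
                         cfg["indiv_callrate_min"])
        gt, panel, report = qc_filter(gt, panel, opts)
        manifest["counts"]["qc_snps"] = gt.n_snps
        manifest["counts"]["qc_individuals"] = gt.n_individuals
        manifest["counts"]["qc_removed"] = report.removed

        stage = "ihs"
        ancestral = read_ancestral(cfg["ancestral"]) if "ancestral" in cfg else None
        ihs_df = scan_panel(panel, n_perm=cfg["n_perm"], seed=cfg["seed"],
                            cutoff=cfg["cutoff"], ancestral=ancestral)
        ihs_df.to_csv(out / "ihs.tsv", sep="\t", index=False)
        manifest["counts"]["ihs_records"] = int(ihs_df["p_ihs"].notna().sum())

        stage = "wga"
        pheno = read_phenotypes(cfg["phenotypes"])
        ped = read_pedigree(cfg["pedigree"])
        G = load_grm(cfg["grm_file"]) if "grm_file" in cfg else None
        wga_df = association_scan(gt, pheno, model=cfg["model"], ped=ped, G=G,
                                  min_family=cfg["min_family"], seed=cfg["seed"])
        wga_df.to_csv(out / "wga.tsv", sep="\t", index=False)
        manifest["counts"]["wga_records"] = int(wga_df["p_asymptotic"].notna().sum())
        manifest["counts"]["lambda_wga"] = inflation_factor(wga_df["t2"])
        qq_table(wga_df["p_asymptotic"].dropna()).to_csv(
            out / "qq_wga.tsv", sep="\t", index=False
        )

        stage = "combine"
        comb, summary = combine_scan(ihs_df, wga_df, cfg["fdr_method"],
                                     cfg["q_threshold"])
        comb.to_csv(out / "combined.tsv", sep="\t", index=False)
        comb[["chrom", "pos_bp", "p_comb"]].assign(
            neglog10_p=-np.log10(comb["p_comb"])
        ).to_csv(out / "manhattan.tsv", sep="\t", index=False)
        qq_table(comb["p_comb"]).to_csv(out / "qq_combined.tsv", sep="\t",
                                        index=False)
        manifest["counts"].update({f"combine_{k}": v for k, v in summary.items()})
    except Exception:
        log.error("pipeline failed in stage %r (partial outputs kept)", stage)
        manifest["failed_stage"] = stage
        manifest["stopped"] = _dt.datetime.now().isoformat(timespec="seconds")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    manifest["stopped"] = _dt.datetime.now().isoformat(timespec="seconds")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
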