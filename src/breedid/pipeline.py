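"""Full-workflow orchestration: QC -> marker selection -> evaluation -> GBC.

`run_pipeline` executes the stages in order on files (VCF or genotype TSV
plus a labels TSV), writes every stage output under the configured
directory, and records a JSON run manifest with the config echo, seeds,
per-stage SNP counts and package version, so a run is reproducible and
auditable.  `validate_config` checks paths, ranges and cross-field
constraints up front and aggregates every problem into one report.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

from . import __version__
from . import classification as cls
from . import gbc as gbc_mod
from . import genotype_io as gio
from . import informativeness as inf

__all__ = ["RunConfig", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    ref_genotypes: str = ""
    ref_labels: str = ""
    test_genotypes: str = ""
    test_labels: str = ""
    out_dir: str = "breedid_out"
    qc: gio.QCConfig = field(default_factory=gio.QCConfig)
    run_ld_prune: bool = False  # windowed pruning is costly on big inputs
    selection: str = "dfi"  # delta | fst | in | dfi
    m_values: list[int] = field(default_factory=lambda: [200, 500, 1000, 1500, 2000])
    methods: list[str] = field(default_factory=lambda: ["knn", "svm", "rf", "ksr"])
    replicates: int = 50
    per_breed_n: int | None = None  # subsample the reference to this size
    subsample_repeats: int = 3
    run_gbc: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        qc_raw = raw.pop("qc", None)
        cfg = cls(**raw)
        if qc_raw:
            if "autosome_names" in qc_raw:
                qc_raw["autosome_names"] = frozenset(str(c) for c in qc_raw["autosome_names"])
            cfg.qc = gio.QCConfig(**qc_raw)
        return cfg


def validate_config(cfg: RunConfig) -> list[str]:
    """All validation problems as human-readable strings (empty = valid)."""
    problems: list[str] = []
    for label, path in [
        ("ref_genotypes", cfg.ref_genotypes),
        ("ref_labels", cfg.ref_labels),
        ("test_genotypes", cfg.test_genotypes),
        ("test_labels", cfg.test_labels),
    ]:
        if not path:
            problems.append(f"{label}: path not set")
        elif not os.path.exists(path):
            problems.append(f"{label}: file not found: {path}")
    if cfg.selection not in ("delta", "fst", "in", "dfi"):
        problems.append(f"selection: unknown method {cfg.selection!r}")
    if cfg.replicates < 1:
        problems.append(f"replicates: must be >= 1, got {cfg.replicates}")
    if not cfg.m_values or any(m < 1 for m in cfg.m_values):
        problems.append(f"m_values: need positive panel sizes, got {cfg.m_values}")
    bad = [m for m in cfg.methods if m not in cls.CLASSIFIERS + ("ksr",)]
    if bad:
        problems.append(f"methods: unknown {bad}")
    if cfg.per_breed_n is not None and cfg.per_breed_n < 1:
        problems.append("per_breed_n: must be >= 1 when set")
    return problems


def _read_genotypes(path: str) -> gio.GenotypeMatrix:
    if path.endswith((".tsv", ".txt")):
        return gio.read_tsv(path)
    return gio.read_vcf(path)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": _config_echo(cfg),
        "stages": {},
    }

    def stage(name):
        manifest["stages"][name] = entry = {}
        return entry

    try:
        entry = stage("load")
        ref = _read_genotypes(cfg.ref_genotypes)
        ref_labels = gio.read_labels(cfg.ref_labels)
        ref_labels.validate_against(ref)
        test = _read_genotypes(cfg.test_genotypes)
        test_labels = gio.read_labels(cfg.test_labels)
        test_labels.validate_against(test)
        entry.update(
            ref_samples=ref.n_samples, test_samples=test.n_samples,
            input_snps=ref.n_snps, breeds=ref_labels.breeds,
        )

        entry = stage("qc")
        ref, report = gio.qc_basic(ref, cfg.qc)
        ref = gio.maf_filter(ref, cfg.qc.maf_min)
        n_after_maf = ref.n_snps
        if cfg.run_ld_prune:
            ref = gio.ld_prune(ref, cfg.qc)
        entry.update(
            removed_non_biallelic=report.removed_non_biallelic,
            removed_missingness=report.removed_missingness,
            removed_non_autosomal=report.removed_non_autosomal,
            removed_maf=report.retained - n_after_maf,
            removed_ld=n_after_maf - ref.n_snps,
            retained=ref.n_snps,
        )
        test_aligned, n_absent = gio.subset_to_positions(test, ref.positions())
        entry["test_snps_aligned"] = test_aligned.n_snps

        if cfg.per_breed_n is not None:
            subsets = cls.subsample_reference(
                ref, ref_labels, cfg.per_breed_n, cfg.subsample_repeats, seed=cfg.seed
            )
        else:
            subsets = [(ref, ref_labels)]

        entry = stage("selection")
        ref_freqs = gio.allele_frequencies(ref, ref_labels)
        scores = inf.compute_scores(ref_freqs)
        scores.to_dataframe().to_csv(
            os.path.join(cfg.out_dir, "scores.tsv"), sep="\t", index=False
        )
        dist = inf.pairwise_fst_matrix(ref_freqs)
        dist.to_dataframe().to_csv(os.path.join(cfg.out_dir, "breed_distances.tsv"), sep="\t")
        panels = {}
        for m in cfg.m_values:
            if m > ref.n_snps:
                raise ValueError(f"M={m} exceeds {ref.n_snps} post-filter SNPs")
            if cfg.selection == "dfi":
                panel = inf.dfi_panel(scores, m)
            else:
                panel = inf.rank_select_top_m(scores, cfg.selection, m)
            panels[m] = panel
            panel.to_dataframe().to_csv(
                os.path.join(cfg.out_dir, f"panel_{cfg.selection}_M{m}.tsv"),
                sep="\t", index=False,
            )
        entry.update(
            method=cfg.selection,
            panels={str(m): {"size": p.m, "depth": p.depth} for m, p in panels.items()},
        )

        entry = stage("evaluation")
        rows = []
        for m, panel in panels.items():
            for si, (sub_ref, sub_labels) in enumerate(subsets):
                reports = cls.evaluate(
                    sub_ref, sub_labels, test_aligned, test_labels, panel,
                    methods=cfg.methods, replicates=cfg.replicates,
                    base_seed=cfg.seed,
                )
                for meth, rep in reports.items():
                    rows.append(
                        {
                            "M": m, "subset": si, "method": meth,
                            "accuracy_mean": round(rep.accuracy_mean, 4),
                            "accuracy_se": round(rep.accuracy_se, 4),
                            "n_test": rep.n_test,
                        }
                    )
        import pandas as pd

        eval_df = pd.DataFrame(rows)
        eval_df.to_csv(os.path.join(cfg.out_dir, "evaluation.tsv"), sep="\t", index=False)
        entry["rows"] = len(rows)

        if cfg.run_gbc:
            entry = stage("gbc")
            table = gbc_mod.gbc_table(test_aligned, test_labels, ref_freqs)
            table.round(2).to_csv(os.path.join(cfg.out_dir, "gbc_table.tsv"), sep="\t")
            entry["animals"] = test_aligned.n_samples
    except Exception as err:
        failed = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {err}") from err

    with open(os.path.join(cfg.out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _config_echo(cfg: RunConfig) -> dict:
    echo = dataclasses.asdict(cfg)
    echo["qc"]["autosome_names"] = sorted(echo["qc"]["autosome_names"])
    return echo
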