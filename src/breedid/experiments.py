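"""End-to-end simulation experiments shared by tests and scripts.

These helpers wire the whole two-stage pipeline together on simulated
breeds: draw Balding–Nichols frequencies, sample reference and test
genotypes, select a marker panel from the reference, train the
classifiers, and score test-set accuracy.  They exist so the same
experiment definition backs both the test suite and reproduction scripts.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import classification as cls
from . import informativeness as inf
from .genotype_io import allele_frequencies
from .synthetic import SimulationConfig, simulate_breed_frequencies, simulate_genotypes

__all__ = ["PipelineResult", "simulated_pipeline_accuracy"]


@dataclass
class PipelineResult:
    """Accuracies (percent) of one simulated pipeline run, per method."""

    accuracy: dict[str, float]
    panel_depth: int | None
    n_test: int


def simulated_pipeline_accuracy(
    seed: int,
    drift: float = 0.2,
    n_breeds: int = 5,
    n_snps: int = 5000,
    n_train: int = 30,
    n_test: int = 50,
    m: int = 500,
    selection: str = "dfi",
    methods: tuple[str, ...] = ("knn", "svm", "rf", "ksr"),
) -> PipelineResult:
    """Run select-train-predict once on a fresh simulated K-breed dataset.

    The reference population (``n_train`` per breed) both selects the
    marker panel and trains the classifiers; accuracy is scored on the
    disjoint test population (``n_test`` per breed).  A single replicate
    is run (the panel and data are fixed given the seed).
    """
    cfg = SimulationConfig(
        n_breeds=n_breeds, n_snps=n_snps, drift=drift, seed=seed
    )
    true_freqs = simulate_breed_frequencies(cfg)
    counts_train = {b: n_train for b in cfg.breed_names}
    counts_test = {b: n_test for b in cfg.breed_names}
    ref, ref_labels = simulate_genotypes(true_freqs, counts_train, seed=seed + 1, id_prefix="R")
    test, test_labels = simulate_genotypes(true_freqs, counts_test, seed=seed + 2, id_prefix="T")

    ref_freqs = allele_frequencies(ref, ref_labels)
    if selection == "dfi":
        panel = inf.dfi_panel(ref_freqs, m)
    else:
        panel = inf.rank_select_top_m(inf.compute_scores(ref_freqs), selection, m)

    reports = cls.evaluate(
        ref, ref_labels, test, test_labels, panel,
        methods=methods, replicates=1, base_seed=seed,
    )
    return PipelineResult(
        accuracy={meth: rep.accuracy_mean for meth, rep in reports.items()},
        panel_depth=panel.depth,
        n_test=len(test.samples),
    )
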