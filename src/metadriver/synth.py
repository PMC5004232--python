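"""Seeded synthetic cohorts with planted ground truth.

The generator emulates the statistical structure the pipeline assumes: a
two-group cohort (high-risk HRM vs low-risk LRM) carrying

* planted driver mutations with pairwise-disjoint HRM carrier sets that
  jointly cover the HRM group (mutual exclusivity + full coverage),
* planted co-expression modules of fold-changed genes driven by a latent
  per-module TF activity (so the module is both differentially expressed
  and tightly co-expressed in HRM samples),
* a protein-interaction network containing guaranteed simple paths from
  each planted driver gene to its module's TF through genes co-expressed
  with that TF (high Pearson edge weights), plus decoy mutant genes whose
  paths run through uncorrelated genes (low weights), on top of an
  Erdős–Rényi background,
* Bernoulli passenger mutations, a handful of germline/region/population
  contaminant variants exercising every somatic filter, and decoy TFs with
  targets disjoint from the planted modules.

All randomness flows from a single integer seed through independent
substreams, so each artifact is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import HRM, LRM, CohortLabels, VariantRecord


@dataclass(frozen=True)
class PlantedScenario:
    """Ground-truth description of a synthetic cohort.

    Defaults mirror the study conditions: a 22/56 cohort, three exclusive
    planted drivers covering all HRM samples, fold-4 planted modules of 10
    genes under one TF each, driver→TF paths of ≤3 edges, and a 2%
    passenger mutation rate.
    """

    seed: int = 0
    n_hrm: int = 22
    n_lrm: int = 56
    driver_carriers: tuple[int, ...] = (8, 7, 7)
    n_modules: int = 3
    module_size: int = 10
    fold_change: float = 4.0
    noise_sd: float = 0.5
    base_expression: float = 10.0
    coexpr_loading: float = 2.0
    background_noise_sd: float = 1.0
    n_background_genes: int = 60
    n_decoy_tfs: int = 3
    decoy_tf_targets: int = 10
    n_decoy_mutants: int = 5
    path_length: int = 3  # edges from driver to TF
    passenger_rate: float = 0.02
    n_passenger_mutations: int = 40
    n_contaminants: int = 10
    ppi_background_p: float = 0.03

    def __post_init__(self) -> None:
        if sum(self.driver_carriers) > self.n_hrm:
            raise ValueError("driver carrier sets exceed the HRM group size")
        if self.path_length < 1:
            raise ValueError("path_length must be ≥ 1")

    # --- deterministic gene naming -------------------------------------
    def hrm_samples(self) -> list[str]:
        return [f"HRM{i:02d}" for i in range(1, self.n_hrm + 1)]

    def lrm_samples(self) -> list[str]:
        return [f"LRM{i:02d}" for i in range(1, self.n_lrm + 1)]

    def driver_genes(self) -> list[str]:
        return [f"DRV{d}" for d in range(len(self.driver_carriers))]

    def planted_drivers(self) -> list[tuple[str, str]]:
        return [(g, f"p.D{d}V") for d, g in enumerate(self.driver_genes())]

    def driver_carrier_sets(self) -> list[list[str]]:
        hrm = self.hrm_samples()
        sets, start = [], 0
        for size in self.driver_carriers:
            sets.append(hrm[start : start + size])
            start += size
        return sets

    def tf_genes(self) -> list[str]:
        return [f"TF{t}" for t in range(self.n_modules)]

    def module_genes(self, t: int) -> list[str]:
        return [f"MOD{t}_G{i:02d}" for i in range(self.module_size)]

    def path_genes(self, d: int) -> list[str]:
        return [f"PATH{d}_{k}" for k in range(self.path_length - 1)]

    def decoy_mutant_genes(self) -> list[str]:
        return [f"DEC{j}" for j in range(self.n_decoy_mutants)]

    def decoy_path_genes(self, j: int) -> list[str]:
        return [f"DPATH{j}_{k}" for k in range(self.path_length - 1)]

    def background_genes(self) -> list[str]:
        return [f"BG{i:03d}" for i in range(self.n_background_genes)]

    def decoy_tf_names(self) -> list[str]:
        return [f"DTF{j}" for j in range(self.n_decoy_tfs)]

    def expressed_genes(self) -> list[str]:
        genes: list[str] = []
        for t in range(self.n_modules):
            genes += self.module_genes(t)
        genes += self.tf_genes()
        genes += self.driver_genes()
        for d in range(len(self.driver_carriers)):
            genes += self.path_genes(d)
        genes += self.decoy_mutant_genes()
        for j in range(self.n_decoy_mutants):
            genes += self.decoy_path_genes(j)
        genes += self.background_genes()
        return genes

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class SyntheticCohort:
    tumor_variants: list[VariantRecord]
    normal_variants: list[VariantRecord]
    labels: CohortLabels
    expression: pd.DataFrame
    truth: dict = field(default_factory=dict)


def generate_cohort(sc: PlantedScenario) -> SyntheticCohort:
    """Variants, labels and FPKM expression for the planted scenario.

    Planted drivers appear only in their assigned HRM samples; decoy
    mutants in exactly two fixed HRM samples each (so they pass the
    group-specific rule); passengers are Bernoulli(passenger_rate) in all
    samples on genes outside the interactome; contaminants exercise the
    germline / population-frequency / class / region filters and are all
    removed by correct filtering.
    """
    hrm, lrm = sc.hrm_samples(), sc.lrm_samples()
    samples = hrm + lrm
    labels = CohortLabels({s: (HRM if s in set(hrm) else LRM) for s in samples})

    tumor: list[VariantRecord] = []
    normal: list[VariantRecord] = []

    for (gene, pchg), carriers in zip(sc.planted_drivers(), sc.driver_carrier_sets()):
        for s in carriers:
            tumor.append(VariantRecord(s, gene, pchg, "missense", "exon", 0.001))

    for j, gene in enumerate(sc.decoy_mutant_genes()):
        for k in range(2):
            s = hrm[(2 * j + k) % sc.n_hrm]
            tumor.append(VariantRecord(s, gene, f"p.E{j}K", "missense", "exon", None))

    rng = sc._rng(1)
    for i in range(sc.n_passenger_mutations):
        gene, pchg = f"PASS{i:03d}", "p.P1L"
        carriers = rng.random(len(samples)) < sc.passenger_rate
        for s, hit in zip(samples, carriers):
            if hit:
                tumor.append(VariantRecord(s, gene, pchg, "missense", "exon", 0.0))

    # contaminants, one filter violation each, cycling through the rules
    rng_c = sc._rng(2)
    for i in range(sc.n_contaminants):
        s = samples[int(rng_c.integers(len(samples)))]
        kind = i % 4
        if kind == 0:  # present in matched normal
            v = VariantRecord(s, f"GERM{i}", "p.G1R", "missense", "exon", None)
            tumor.append(v)
            normal.append(v)
        elif kind == 1:  # common population variant
            tumor.append(VariantRecord(s, f"COMMON{i}", "p.C1S", "missense", "exon", 0.35))
        elif kind == 2:  # synonymous
            tumor.append(VariantRecord(s, f"SYN{i}", "p.S1S", "synonymous", "exon", None))
        else:  # intronic / other region
            tumor.append(VariantRecord(s, f"INTRON{i}", "p.I1I", "missense", "other", None))

    expression = _generate_expression(sc, samples, set(hrm))
    truth = {
        "drivers": sc.planted_drivers(),
        "decoy_mutants": sc.decoy_mutant_genes(),
        "deg_genes": [g for t in range(sc.n_modules) for g in sc.module_genes(t)],
        "tfs": sc.tf_genes(),
    }
    return SyntheticCohort(tumor, normal, labels, expression, truth)


def _generate_expression(
    sc: PlantedScenario, samples: list[str], hrm: set[str]
) -> pd.DataFrame:
    rng = sc._rng(3)
    genes = sc.expressed_genes()
    n = len(samples)
    activity = rng.standard_normal((sc.n_modules, n))  # latent TF activity
    data = {}
    is_hrm = np.array([s in hrm for s in samples])

    def correlated(t: int, shifted: bool) -> np.ndarray:
        base = sc.base_expression * np.where(
            is_hrm & shifted, sc.fold_change, 1.0
        )
        return base + sc.coexpr_loading * activity[t] + rng.normal(0, sc.noise_sd, n)

    for t in range(sc.n_modules):
        for g in sc.module_genes(t):
            data[g] = correlated(t, shifted=True)
        data[f"TF{t}"] = correlated(t, shifted=False)
    for d in range(len(sc.driver_carriers)):
        t = d % sc.n_modules
        data[sc.driver_genes()[d]] = correlated(t, shifted=False)
        for g in sc.path_genes(d):
            data[g] = correlated(t, shifted=False)
    noise_genes = (
        sc.decoy_mutant_genes()
        + [g for j in range(sc.n_decoy_mutants) for g in sc.decoy_path_genes(j)]
        + sc.background_genes()
    )
    for g in noise_genes:
        data[g] = sc.base_expression + rng.normal(0, sc.background_noise_sd, n)

    matrix = pd.DataFrame(data, index=samples).T.clip(lower=0.0)
    matrix.index.name = "gene"
    return matrix.loc[genes]


def generate_ppi(sc: PlantedScenario) -> nx.Graph:
    """Interactome with planted driver→TF and decoy→TF simple paths.

    Background edges are Erdős–Rényi with probability ``ppi_background_p``
    over all expressed genes; planted path edges are always present.
    """
    genes = sc.expressed_genes()
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for d, driver in enumerate(sc.driver_genes()):
        chain = [driver] + sc.path_genes(d) + [f"TF{d % sc.n_modules}"]
        nx.add_path(graph, chain)
    for j, decoy in enumerate(sc.decoy_mutant_genes()):
        chain = [decoy] + sc.decoy_path_genes(j) + [f"TF{j % sc.n_modules}"]
        nx.add_path(graph, chain)
    if sc.ppi_background_p > 0:
        rng = sc._rng(4)
        arr = np.array(genes)
        for i in range(len(arr)):
            hits = rng.random(len(arr) - i - 1) < sc.ppi_background_p
            for off in np.nonzero(hits)[0]:
                graph.add_edge(arr[i], arr[i + 1 + off])
    return graph


def generate_tf_targets(sc: PlantedScenario) -> dict[str, frozenset[str]]:
    """Planted TFs target their module genes; decoy TFs target background genes."""
    tfmap: dict[str, frozenset[str]] = {}
    for t in range(sc.n_modules):
        tfmap[f"TF{t}"] = frozenset(sc.module_genes(t))
    rng = sc._rng(5)
    background = sc.background_genes()
    for j, name in enumerate(sc.decoy_tf_names()):
        pick = rng.choice(len(background), size=min(sc.decoy_tf_targets, len(background)), replace=False)
        tfmap[name] = frozenset(background[i] for i in sorted(pick))
    return tfmap
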