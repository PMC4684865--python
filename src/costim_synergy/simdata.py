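"""Synthetic two-channel microarray experiments with known ground truth.

Emulates a TLR7-ligand costimulation study on a pDC cell line: triplicate
two-colour arrays for an untreated control, two single-ligand treatments
(ligand A = a weak ssRNA ligand, ligand B = a potent base-analog ligand)
and their combination, over a shared gene universe.  A configurable
fraction of genes responds to each ligand, and a distinct class responds
supra-additively to the combination, so that every downstream stage —
normalization, upregulation calling, recruitment accounting, synergy
classification and network coverage — can be validated against latent
truth without any external data.

Randomness discipline
---------------------
A single global seed drives everything.  Substreams are derived as
``default_rng(SeedSequence(seed, spawn_key=(k,)))`` with ``k = 0`` for the
truth draw and ``k = 1 + i`` for the i-th array in design order
(conditions in ``CONDITIONS`` order, replicates innermost).  Within each
stream the draw order is fixed and documented on the operation, so any
individual quantity can be re-derived independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import SpotTable, write_spot_table
from .netreg import RegNetwork

CONDITIONS = ("control", "ligand_a", "ligand_b", "combo")

CLASS_NULL = "null"
CLASS_ADDITIVE = "additive"
CLASS_SUPRA = "supra_additive"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated costimulation experiment.

    Defaults describe the regime of the emulated study: a gene universe of
    10,000 spotted genes measured in triplicate per condition, a weak
    ligand A regulating ~0.15% of genes, a potent ligand B regulating ~1%,
    and ~2.5% of genes responding supra-additively to costimulation
    (about a third of which also respond to ligand B alone), with log2
    effect sizes around 2 (fold changes mostly 2-15), low replicate noise
    of 0.1 on the log2 scale typical of cell-line triplicates, an
    intensity-dependent dye bias of amplitude 0.3, and small flagged /
    low-intensity spot fractions.
    """

    n_genes: int = 10_000
    frac_regulated_a: float = 0.0015
    frac_regulated_b: float = 0.011
    frac_supra: float = 0.025
    #: supra-additive genes may also respond to a single ligand; these are
    #: the conditional regulation probabilities for that class (the potent
    #: ligand B drives most of the single-ligand response among genes that
    #: end up synergistic, the weak ligand A rarely does)
    p_reg_a_given_supra: float = 0.05
    p_reg_b_given_supra: float = 0.30
    effect_log2_mean: float = 2.0
    effect_log2_sd: float = 0.9
    #: supra-additive multiplier s is drawn uniform on [supra_min, supra_max];
    #: fc_combo = s * (fc_a + fc_b)
    supra_min: float = 1.5
    supra_max: float = 5.0
    noise_sd: float = 0.1
    baseline_log_mean: float = 9.0
    baseline_log_sd: float = 1.5
    #: additive scanner/hybridization background present in both channels,
    #: the target of the background-correction step
    background_level: float = 80.0
    dye_bias_amplitude: float = 0.3
    flag_rate: float = 0.02
    low_intensity_rate: float = 0.02
    n_replicates: int = 3
    #: combination rule for genes regulated by a ligand but not supra-additive:
    #: "additive" gives fc_combo = fc_a + fc_b - 1, "log_additive" fc_a * fc_b
    combine: str = "additive"
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "frac_regulated_a": self.frac_regulated_a,
            "frac_regulated_b": self.frac_regulated_b,
            "frac_supra": self.frac_supra,
            "p_reg_a_given_supra": self.p_reg_a_given_supra,
            "p_reg_b_given_supra": self.p_reg_b_given_supra,
            "flag_rate": self.flag_rate,
            "low_intensity_rate": self.low_intensity_rate,
        }
        for name, v in fracs.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_regulated_a + self.frac_regulated_b + self.frac_supra > 1:
            raise ValueError("regulated-gene fractions sum above 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 1.5 <= self.supra_min <= self.supra_max:
            raise ValueError("need 1.5 <= supra_min <= supra_max")
        if self.combine not in ("additive", "log_additive"):
            raise ValueError("combine must be 'additive' or 'log_additive'")


@dataclass
class SimTruth:
    """Latent per-gene fold changes and synergy class behind a simulation.

    ``fc_combo`` relates to the single-ligand fold changes by class:
    null genes sit at 1 everywhere; additive genes combine as
    fc_a + fc_b - 1 (or multiplicatively under the log-additive option);
    supra-additive genes satisfy fc_combo >= 1.5 * (fc_a + fc_b).
    """

    gene_ids: list[str]
    fc_a: np.ndarray
    fc_b: np.ndarray
    fc_combo: np.ndarray
    synergy_class: np.ndarray
    #: per-gene log2 reference-channel abundance; the common reference cDNA
    #: is the same material on every array, so this is a gene property
    baseline_log2: np.ndarray | None = None
    seed: int = 0

    def fold_change(self, condition: str) -> np.ndarray:
        if condition == "control":
            return np.ones(len(self.gene_ids))
        return {"ligand_a": self.fc_a, "ligand_b": self.fc_b,
                "combo": self.fc_combo}[condition]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fc_a": self.fc_a, "fc_b": self.fc_b, "fc_combo": self.fc_combo,
             "synergy_class": self.synergy_class},
            index=pd.Index(self.gene_ids, name="gene_id"),
        )


def substream(seed: int, k: int) -> np.random.Generator:
    """The documented k-th random substream of a global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))


def dye_bias_profile(a: np.ndarray, amplitude: float, center: float) -> np.ndarray:
    """Smooth intensity-dependent bias added to log2 ratios.

    A slow sinusoid of the mean log2 intensity A, one period across roughly
    the occupied intensity range, mimicking the curved M-A trend produced
    by unequal Cy3/Cy5 labelling efficiencies.  Exposed so tests can
    subtract the injected bias analytically.
    """
    return amplitude * np.sin((np.asarray(a, float) - center) / 1.5)


def default_gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def simulate_truth(config: SimConfig) -> SimTruth:
    """Draw latent per-gene classes and fold changes.

    Draw order within substream 0: (1) n uniforms for the supra-additive
    class, (2) n uniforms for ligand-A regulation, (3) n uniforms for
    ligand-B regulation, (4) n log2 effects for A, (5) n log2 effects for
    B, (6) n supra multipliers, (7) n baseline log2 abundances.
    """
    rng = substream(config.seed, 0)
    n = config.n_genes
    is_supra = rng.random(n) < config.frac_supra
    p_a = np.where(is_supra, config.p_reg_a_given_supra, config.frac_regulated_a)
    p_b = np.where(is_supra, config.p_reg_b_given_supra, config.frac_regulated_b)
    reg_a = rng.random(n) < p_a
    reg_b = rng.random(n) < p_b
    eff_a = np.exp2(rng.normal(config.effect_log2_mean, config.effect_log2_sd, n))
    eff_b = np.exp2(rng.normal(config.effect_log2_mean, config.effect_log2_sd, n))
    s = rng.uniform(config.supra_min, config.supra_max, n)

    fc_a = np.where(reg_a, eff_a, 1.0)
    fc_b = np.where(reg_b, eff_b, 1.0)
    if config.combine == "additive":
        fc_combo_add = fc_a + fc_b - 1.0
    else:
        fc_combo_add = fc_a * fc_b
    fc_combo = np.where(is_supra, s * (fc_a + fc_b), fc_combo_add)
    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, n)

    klass = np.full(n, CLASS_NULL, dtype=object)
    klass[reg_a | reg_b] = CLASS_ADDITIVE
    klass[is_supra] = CLASS_SUPRA
    # null genes stay flat under every condition
    null = klass == CLASS_NULL
    fc_a[null] = fc_b[null] = fc_combo[null] = 1.0

    return SimTruth(default_gene_ids(n), fc_a, fc_b, fc_combo,
                    klass, baseline_log2=baseline, seed=config.seed)


def design_table(config: SimConfig) -> pd.DataFrame:
    """Array design: conditions in CONDITIONS order, replicates innermost."""
    rows = [
        {"array_id": f"{cond}_r{rep}", "condition": cond, "replicate": rep}
        for cond in CONDITIONS
        for rep in range(1, config.n_replicates + 1)
    ]
    return pd.DataFrame(rows)


def simulate_arrays(truth: SimTruth,
                    config: SimConfig) -> tuple[list[SpotTable], pd.DataFrame]:
    """Simulate one spot table per array of the design.

    For array i (design order) the substream is ``1 + i`` and the draw
    order is: (1) n log2 jitters on the per-gene reference abundance,
    (2) n log2 replicate noise values, (3) n flag uniforms, (4) n
    low-intensity uniforms, (5) 2n uniforms for the low-intensity
    replacement values.

    The sample signal is reference signal x condition fold change x
    2^noise, then multiplied by 2^bias where the bias is the smooth
    :func:`dye_bias_profile` of the spot's pre-bias mean log intensity;
    both channels then receive the additive ``background_level``.
    Low-intensity spots have both channels forced below the conventional
    100-unit filter threshold.
    """
    if len(truth.gene_ids) != config.n_genes:
        raise ValueError("truth and config disagree on n_genes")
    design = design_table(config)
    n = config.n_genes
    base = (truth.baseline_log2 if truth.baseline_log2 is not None
            else np.full(n, config.baseline_log_mean))
    tables: list[SpotTable] = []
    for i, row in design.iterrows():
        rng = substream(config.seed, 1 + int(i))
        fc = truth.fold_change(row["condition"])
        log_ref = base + rng.normal(0.0, config.noise_sd, n)
        noise = rng.normal(0.0, config.noise_sd, n)
        ref = np.exp2(log_ref)
        sample = ref * fc * np.exp2(noise)
        a = 0.5 * np.log2(ref * sample)
        sample = sample * np.exp2(
            dye_bias_profile(a, config.dye_bias_amplitude,
                             config.baseline_log_mean))
        ref = ref + config.background_level
        sample = sample + config.background_level
        flags = rng.random(n) < config.flag_rate
        low = rng.random(n) < config.low_intensity_rate
        low_vals = rng.uniform(5.0, 95.0, size=(n, 2))
        ref = np.where(low, low_vals[:, 0], ref)
        sample = np.where(low, low_vals[:, 1], sample)
        data = pd.DataFrame({
            "gene_id": truth.gene_ids,
            "ch_reference": ref,
            "ch_sample": sample,
            "flag": flags,
        })
        tables.append(SpotTable(row["array_id"], data))
    return tables, design


def simulate_network(gene_universe: list[str],
                     n_major: int,
                     n_minor: int,
                     coverage_major: float = 0.4,
                     coverage_minor: float = 0.15,
                     seed: int = 0,
                     sparse_rate: float = 0.02) -> RegNetwork:
    """Plant major and minor regulatory hubs in a directed network.

    Each designated major node receives directed edges to
    ceil(coverage_major * N) distinct targets (N = universe size, self
    excluded), each minor node to ceil(coverage_minor * N); the remaining
    nodes get sparse random out-edges covering under 10% of the network,
    so the planted classes are recoverable by the coverage thresholds
    (major: >30%, minor: 10% to <30%).
    """
    n = len(gene_universe)
    if coverage_major > 1 or coverage_minor > 1:
        raise ValueError("coverage fractions must be <= 1")
    if not coverage_major > 0.30:
        raise ValueError("coverage_major must exceed 0.30 (major-node threshold)")
    if not 0.10 <= coverage_minor <= 0.30:
        raise ValueError("coverage_minor must lie in [0.10, 0.30]")
    if n_major + n_minor > n:
        raise ValueError("more hub nodes requested than universe members")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    universe = list(gene_universe)
    order = rng.permutation(n)
    majors = [universe[j] for j in order[:n_major]]
    minors = [universe[j] for j in order[n_major:n_major + n_minor]]
    others = [universe[j] for j in order[n_major + n_minor:]]

    edges: set[tuple[str, str]] = set()

    def add_targets(node: str, k: int) -> None:
        candidates = [g for g in universe if g != node]
        targets = rng.choice(len(candidates), size=k, replace=False)
        for t in targets:
            edges.add((node, candidates[t]))

    k_major = math.ceil(coverage_major * n)
    k_minor = math.ceil(coverage_minor * n)
    for node in majors:
        add_targets(node, min(k_major, n - 1))
    for node in minors:
        add_targets(node, min(k_minor, n - 1))
    if sparse_rate > 0:
        cap = max(0, math.ceil(0.10 * (n - 1)) - 1)
        for node in others:
            k = int(min(rng.binomial(n - 1, sparse_rate), cap))
            if k > 0:
                add_targets(node, k)
    return RegNetwork.from_edges(edges, universe)


# ---------------------------------------------------------------------------
# file output


def write_simulation(truth: SimTruth, tables: list[SpotTable],
                     design: pd.DataFrame, outdir: str | Path) -> dict[str, Path]:
    """Write truth, design and per-array spot tables as tab-delimited text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    truth_path = outdir / "truth.tsv"
    truth.to_frame().to_csv(truth_path, sep="\t", float_format="%.6g")
    paths["truth"] = truth_path
    design_path = outdir / "design.tsv"
    design.to_csv(design_path, sep="\t", index=False)
    paths["design"] = design_path
    for spots in tables:
        p = outdir / f"array_{spots.array_id}.tsv"
        write_spot_table(spots, p)
        paths[spots.array_id] = p
    return paths


def write_network(network: RegNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\n")
        for reg, tgt in sorted(network.edges):
            fh.write(f"{reg}\t{tgt}\n")
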