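"""Synthetic data generators with known ground truth.

Two experiment types are emulated:

* A pooled CRISPR knockout screen run in two genetic backgrounds (control and
  sensitized/"treated"), with a Brunello-like guide library (~4 guides per
  gene plus non-targeting controls), log-normal plasmid abundances, an
  exponential selection phase over a fixed number of population doublings, and
  multinomial or negative-binomial sequencing noise.

* A multiplexed TMT proteomics experiment (duplicate control vs. treated
  channels) quantified at peptide level as reporter-ion signal-to-noise, with
  configurable cross-channel isotope-impurity mixing and designated gene sets
  (e.g. Fe-S cluster proteins, mitoribosomal SSU) carrying a known log10
  fold-change shift.

Every generator records a truth table sufficient to check full parameter
recovery downstream, and is bitwise-reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tmt import impurity_matrix_from_spillover

__all__ = [
    "SCREEN_SAMPLES",
    "NTC_PREFIX",
    "ScreenSimConfig",
    "ScreenDataset",
    "ProteomicsSimConfig",
    "TMTDataset",
    "paper_scale_config",
    "gen_screen_dataset",
    "expected_screen_dataset",
    "gen_expression_table",
    "expression_for_screen",
    "gen_proteomics_dataset",
    "default_sim_genesets",
    "expected_coverage",
]

#: Sample (column) layout of a simulated screen: one shared plasmid library
#: reference plus paired selection replicates in each background.
SCREEN_SAMPLES = ("plasmid", "ctrl_rep1", "ctrl_rep2", "treat_rep1", "treat_rep2")

#: Reserved gene-label prefix for non-targeting control pseudo-genes.
NTC_PREFIX = "NTC"

_CLASSES = ("neutral", "essential", "buffering", "synthetic_sick")


@dataclass(frozen=True)
class ScreenSimConfig:
    """Parameters of the pooled-screen simulation.

    Attributes
    ----------
    n_genes:
        Number of targeted genes.
    guides_per_gene:
        Guides designed per gene (library average if ``n_targeting`` is set).
    n_targeting:
        Optional exact total of targeting guides, distributed near-evenly
        over genes (used by the paper-scale preset, where the printed library
        total is not a multiple of 4). ``None`` means
        ``n_genes * guides_per_gene``.
    n_ntc:
        Non-targeting control guides, grouped into neutral pseudo-genes of
        ``guides_per_gene`` guides under the reserved ``NTC`` prefix.
    plasmid_lognormal_sigma:
        Log-normal sigma (natural log) of per-guide plasmid abundance.
    doublings:
        Population doublings ``d`` during the selection phase.
    frac_essential, frac_buffering, frac_synthetic_sick:
        Gene-class proportions; the remainder is neutral.
    frac_nonexpressed:
        Fraction of genes flagged as non-expressed (drawn from the neutral
        class: knocking out a silent gene has no fitness effect). These genes
        define the empirical null downstream.
    essential_fitness:
        Base per-doubling fitness ``f`` of essential and buffering genes
        (negative = depleted).
    interaction_effect:
        Interaction fitness ``gamma`` added in the treated background:
        buffering genes get ``+gamma``, synthetic-sick genes ``-gamma``.
    guide_efficiency_beta:
        ``(a, b)`` of the Beta distribution of per-guide cutting efficiency
        ``e``; ``None`` fixes every efficiency to 1.
    seq_depth:
        Reads per sequenced sample.
    noise_model:
        ``"multinomial"`` (column sums exactly ``seq_depth``) or
        ``"negative_binomial"`` (PCR/sequencing overdispersion).
    nb_dispersion:
        NB dispersion ``alpha`` with ``var = mu + alpha * mu**2``.
    """

    n_genes: int = 2000
    guides_per_gene: int = 4
    n_targeting: int | None = None
    n_ntc: int = 1000
    plasmid_lognormal_sigma: float = 0.5
    doublings: float = 10.0
    frac_essential: float = 0.10
    frac_buffering: float = 0.05
    frac_synthetic_sick: float = 0.05
    frac_nonexpressed: float = 0.20
    essential_fitness: float = -0.5
    interaction_effect: float = 0.5
    guide_efficiency_beta: tuple[float, float] | None = (5.0, 1.0)
    seq_depth: int = 10_000_000
    noise_model: str = "multinomial"
    nb_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.guides_per_gene <= 0:
            raise ValueError("n_genes and guides_per_gene must be positive")
        if self.n_ntc < 0:
            raise ValueError("n_ntc must be non-negative")
        if self.seq_depth <= 0:
            raise ValueError("seq_depth must be positive")
        if self.plasmid_lognormal_sigma <= 0:
            raise ValueError("plasmid_lognormal_sigma must be positive")
        if self.doublings <= 0:
            raise ValueError("doublings must be positive")
        fracs = (self.frac_essential, self.frac_buffering, self.frac_synthetic_sick)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("class fractions must lie in [0, 1]")
        if sum(fracs) > 1:
            raise ValueError("class fractions must sum to <= 1")
        if not 0 <= self.frac_nonexpressed <= 1:
            raise ValueError("frac_nonexpressed must lie in [0, 1]")
        if self.noise_model not in ("multinomial", "negative_binomial"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_targeting is not None and self.n_targeting < self.n_genes:
            raise ValueError("n_targeting must allow >= 1 guide per gene")

    @property
    def total_targeting(self) -> int:
        if self.n_targeting is not None:
            return self.n_targeting
        return self.n_genes * self.guides_per_gene

    @property
    def total_guides(self) -> int:
        return self.total_targeting + self.n_ntc


def paper_scale_config(**overrides) -> ScreenSimConfig:
    """Preset reproducing the Brunello library composition.

    77,441 sgRNAs in total: 76,441 targeting guides over 19,114 genes
    (average ~4 per gene) plus 1,000 non-targeting controls.
    """
    params = dict(n_genes=19114, guides_per_gene=4, n_targeting=76441, n_ntc=1000)
    params.update(overrides)
    return ScreenSimConfig(**params)


@dataclass
class ScreenDataset:
    """Guide x sample counts with guide->gene map and simulation truth.

    ``counts`` columns follow :data:`SCREEN_SAMPLES`; ``truth`` is indexed by
    gene with columns ``fitness`` (f), ``gamma``, ``gclass``, ``expressed``
    and ``is_ntc``.
    """

    counts: pd.DataFrame
    guide_map: pd.Series
    truth: pd.DataFrame | None = None
    guide_stats: pd.DataFrame | None = None
    config: ScreenSimConfig | None = None

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.guide_map.index):
            raise ValueError("counts and guide_map must share a guide index")
        if self.guide_map.index.has_duplicates:
            raise ValueError("duplicate guide identifiers")

    @property
    def genes(self) -> pd.Index:
        return pd.Index(pd.unique(self.guide_map.values))


def _gene_guide_counts(config: ScreenSimConfig) -> np.ndarray:
    """Guides per gene, distributing an exact targeting total near-evenly."""
    n = config.total_targeting
    base, extra = divmod(n, config.n_genes)
    out = np.full(config.n_genes, base, dtype=int)
    out[:extra] += 1
    return out


def _assign_truth(config: ScreenSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    n_ess = round(config.frac_essential * config.n_genes)
    n_buf = round(config.frac_buffering * config.n_genes)
    n_ss = round(config.frac_synthetic_sick * config.n_genes)
    if n_ess + n_buf + n_ss > config.n_genes:
        raise ValueError("class fractions leave no room for neutral genes")
    order = rng.permutation(config.n_genes)
    gclass = np.array(["neutral"] * config.n_genes, dtype=object)
    gclass[order[:n_ess]] = "essential"
    gclass[order[n_ess:n_ess + n_buf]] = "buffering"
    gclass[order[n_ess + n_buf:n_ess + n_buf + n_ss]] = "synthetic_sick"

    fitness = np.where(np.isin(gclass, ("essential", "buffering")),
                       config.essential_fitness, 0.0)
    gamma = np.where(gclass == "buffering", config.interaction_effect, 0.0)
    gamma = np.where(gclass == "synthetic_sick", -config.interaction_effect, gamma)

    # non-expressed genes are neutral by construction (no product, no fitness)
    n_null = round(config.frac_nonexpressed * config.n_genes)
    neutral_idx = np.flatnonzero(gclass == "neutral")
    if n_null > neutral_idx.size:
        raise ValueError("frac_nonexpressed exceeds the neutral gene fraction")
    null_idx = rng.choice(neutral_idx, size=n_null, replace=False)
    expressed = np.ones(config.n_genes, dtype=bool)
    expressed[null_idx] = False

    return pd.DataFrame(
        {"fitness": fitness, "gamma": gamma, "gclass": gclass, "expressed": expressed,
         "is_ntc": False},
        index=pd.Index(genes, name="gene"),
    )


def _build_library(config: ScreenSimConfig, rng: np.random.Generator):
    """Guide names, guide->gene map, per-guide fitness/gamma/efficiency."""
    truth = _assign_truth(config, rng)
    per_gene = _gene_guide_counts(config)

    guide_names: list[str] = []
    guide_gene: list[str] = []
    for gene, k in zip(truth.index, per_gene):
        for j in range(k):
            guide_names.append(f"{gene}_sg{j + 1}")
            guide_gene.append(gene)

    n_ntc_genes = math.ceil(config.n_ntc / config.guides_per_gene) if config.n_ntc else 0
    ntc_rows = []
    g = 0
    for i in range(n_ntc_genes):
        gene = f"{NTC_PREFIX}_{i + 1:04d}"
        ntc_rows.append(gene)
        for j in range(min(config.guides_per_gene, config.n_ntc - g)):
            guide_names.append(f"{gene}_sg{j + 1}")
            guide_gene.append(gene)
            g += 1
    if ntc_rows:
        ntc_truth = pd.DataFrame(
            {"fitness": 0.0, "gamma": 0.0, "gclass": "neutral", "expressed": False,
             "is_ntc": True},
            index=pd.Index(ntc_rows, name="gene"),
        )
        truth = pd.concat([truth, ntc_truth])

    guide_map = pd.Series(guide_gene, index=pd.Index(guide_names, name="guide"),
                          name="gene")
    f = truth["fitness"].reindex(guide_map.values).to_numpy()
    gam = truth["gamma"].reindex(guide_map.values).to_numpy()
    if config.guide_efficiency_beta is None:
        eff = np.ones(len(guide_map))
    else:
        a, b = config.guide_efficiency_beta
        eff = rng.beta(a, b, size=len(guide_map))
    plasmid = rng.lognormal(0.0, config.plasmid_lognormal_sigma, size=len(guide_map))
    return guide_map, truth, f, gam, eff, plasmid


def _expected_fractions(plasmid, f, gam, eff, doublings):
    """Relative post-selection abundance per sample, columns summing to 1."""
    cols = {"plasmid": plasmid / plasmid.sum()}
    for arm, treat in (("ctrl", False), ("treat", True)):
        rate = eff * (f + (gam if treat else 0.0))
        w = plasmid * np.exp2(doublings * rate)
        frac = w / w.sum()
        for rep in (1, 2):
            cols[f"{arm}_rep{rep}"] = frac
    return cols


def _draw_counts(fracs: dict, config: ScreenSimConfig,
                 rng: np.random.Generator) -> dict:
    out = {}
    for name in SCREEN_SAMPLES:
        p = fracs[name]
        if config.noise_model == "multinomial":
            out[name] = rng.multinomial(config.seq_depth, p)
        else:
            mu = config.seq_depth * p
            r = 1.0 / config.nb_dispersion
            out[name] = rng.negative_binomial(r, r / (r + mu))
    return out


def gen_screen_dataset(config: ScreenSimConfig) -> ScreenDataset:
    """Simulate a two-background pooled screen with known per-gene truth.

    Plasmid abundances are log-normal; the expected post-growth relative
    abundance of guide *i* for gene *g* in background *b* is proportional to
    ``plasmid_i * 2**(d * e_i * (f_g + gamma_g * [b == treat]))``; counts are
    drawn per ``config.noise_model``. Identical config and seed give a
    bitwise-identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    guide_map, truth, f, gam, eff, plasmid = _build_library(config, rng)
    fracs = _expected_fractions(plasmid, f, gam, eff, config.doublings)
    counts = pd.DataFrame(_draw_counts(fracs, config, rng),
                          index=guide_map.index, columns=list(SCREEN_SAMPLES))
    stats = pd.DataFrame({"gene": guide_map, "efficiency": eff,
                          "fitness": f, "gamma": gam}, index=guide_map.index)
    return ScreenDataset(counts=counts, guide_map=guide_map, truth=truth,
                         guide_stats=stats, config=config)


def expected_screen_dataset(config: ScreenSimConfig) -> ScreenDataset:
    """Noise-free limit: real-valued expected counts at ``seq_depth``.

    Emulates infinite sequencing depth; downstream guide log2 fold-changes
    equal ``d * e * f`` exactly once the composition offset shared by all
    guides (the log2 mean fold-growth) is removed, e.g. by centering on
    non-targeting controls with a zero pseudocount.
    """
    rng = np.random.default_rng(config.seed)
    guide_map, truth, f, gam, eff, plasmid = _build_library(config, rng)
    fracs = _expected_fractions(plasmid, f, gam, eff, config.doublings)
    counts = pd.DataFrame({k: config.seq_depth * v for k, v in fracs.items()},
                          index=guide_map.index, columns=list(SCREEN_SAMPLES))
    stats = pd.DataFrame({"gene": guide_map, "efficiency": eff,
                          "fitness": f, "gamma": gam}, index=guide_map.index)
    return ScreenDataset(counts=counts, guide_map=guide_map, truth=truth,
                         guide_stats=stats, config=config)


def gen_expression_table(n_genes: int, frac_null: float, floor: float = -7.0,
                         seed: int = 0) -> pd.Series:
    """Gene -> log2 FPKM with exactly ``round(frac_null * n_genes)`` genes at
    the floor value and the rest strictly above it."""
    if not 0 < frac_null < 1:
        raise ValueError("frac_null must lie strictly between 0 and 1")
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"G{i + 1:05d}" for i in range(n_genes)], name="gene")
    n_null = round(frac_null * n_genes)
    values = floor + 0.5 + rng.gamma(2.0, 2.5, size=n_genes)
    null_idx = rng.choice(n_genes, size=n_null, replace=False)
    values[null_idx] = floor
    return pd.Series(values, index=genes, name="log2_fpkm")


def expression_for_screen(dataset: ScreenDataset, floor: float = -7.0,
                          seed: int = 0) -> pd.Series:
    """Expression table aligned with a simulated screen's truth.

    Genes flagged non-expressed in the truth table sit at the FPKM floor;
    expressed genes are strictly above it. NTC pseudo-genes are excluded
    (they are library artifacts, not genes with transcripts).
    """
    if dataset.truth is None:
        raise ValueError("dataset carries no truth table")
    truth = dataset.truth[~dataset.truth["is_ntc"]]
    rng = np.random.default_rng(seed)
    values = floor + 0.5 + rng.gamma(2.0, 2.5, size=len(truth))
    values[~truth["expressed"].to_numpy()] = floor
    return pd.Series(values, index=truth.index.copy(), name="log2_fpkm")


# ---------------------------------------------------------------------------
# TMT proteomics simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteomicsSimConfig:
    """Parameters of the synthetic duplicate ctrl-vs-treat TMT experiment.

    ``set_shifts`` maps gene-set names to the log10 fold-change delta carried
    by member proteins (negative = depleted in the treated channels);
    ``impurity_spillover`` is the fraction of each reagent's reporter signal
    leaking into each adjacent channel; ``peptide_noise_cv`` is the linear-
    scale coefficient of variation of per-channel peptide measurement noise.
    """

    n_proteins: int = 2000
    peptides_per_protein_lambda: float = 2.0
    channels: tuple[str, ...] = ("ctrl", "ctrl", "treat", "treat")
    background_fc_sigma: float = 0.05
    set_shifts: dict = field(default_factory=lambda: {"FES": -0.2, "SSU": -0.2})
    impurity_spillover: float = 0.02
    peptide_noise_cv: float = 0.05
    balance_loading: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if self.peptides_per_protein_lambda <= 0:
            raise ValueError("peptides_per_protein_lambda must be positive")
        if not 0 <= self.impurity_spillover < 0.5:
            raise ValueError("impurity_spillover must lie in [0, 0.5)")
        if self.peptide_noise_cv < 0:
            raise ValueError("peptide_noise_cv must be non-negative")
        if self.background_fc_sigma <= 0:
            raise ValueError("background_fc_sigma must be positive")
        conds = set(self.channels)
        if not {"ctrl", "treat"} <= conds:
            raise ValueError("channels must include both ctrl and treat")


@dataclass
class TMTDataset:
    """Synthetic peptide-level TMT experiment.

    ``peptides`` has columns ``peptide``, ``protein`` and one observed-SN
    column per channel; ``impurity`` is the channel x channel mixing matrix
    actually applied; ``design`` maps channel id -> condition; ``truth`` is
    indexed by protein with the realized log10 fold-change and set labels.
    """

    peptides: pd.DataFrame
    impurity: pd.DataFrame
    design: dict
    truth: pd.DataFrame
    config: ProteomicsSimConfig | None = None


def default_sim_genesets(config: ProteomicsSimConfig,
                         sizes: dict | None = None):
    """Synthetic gene sets over the simulated protein ids.

    By default the first 40 proteins form ``FES``, the next 30 ``SSU`` and the
    following 30 ``LSU`` (an unshifted control set).
    """
    from .shift import GeneSetCollection

    sizes = dict(sizes or {"FES": 40, "SSU": 30, "LSU": 30})
    total = sum(sizes.values())
    if total > config.n_proteins:
        raise ValueError("gene sets exceed the number of simulated proteins")
    proteins = [f"P{i + 1:04d}" for i in range(config.n_proteins)]
    sets, start = {}, 0
    for name, size in sizes.items():
        sets[name] = frozenset(proteins[start:start + size])
        start += size
    return GeneSetCollection(sets=sets, provenance="synthetic")


def _loading_balance_offset(baseline, fc, shifted_mask):
    """log10 offset for background proteins equalizing total channel signal.

    Total treated signal sum(B * 10**fc) is forced equal to the control total
    sum(B) by shifting non-set background fold-changes by a common constant,
    emulating the equal peptide loading of a TMT experiment. Returns the
    offset c with sum_bg B*10**(fc+c) + sum_set B*10**fc == sum(B).
    """
    total = baseline.sum()
    set_signal = (baseline[shifted_mask] * 10.0 ** fc[shifted_mask]).sum()
    bg_signal = (baseline[~shifted_mask] * 10.0 ** fc[~shifted_mask]).sum()
    if bg_signal <= 0 or total - set_signal <= 0:
        raise ValueError("cannot balance loading: shifted sets dominate the signal")
    return math.log10((total - set_signal) / bg_signal)


def gen_proteomics_dataset(config: ProteomicsSimConfig,
                           gene_sets=None) -> TMTDataset:
    """Simulate a peptide-level TMT table with known per-protein truth.

    True peptide SN = protein baseline x peptide factor x 10**(FC * [treat])
    x log-normal noise; the observed table is the impurity matrix applied
    across channels of each peptide row. The truth fold-change is a
    background draw plus the configured shift for set members; background
    fold-changes additionally carry a small common offset that equalizes
    total signal per condition (equal-loading design).
    """
    if gene_sets is None:
        gene_sets = default_sim_genesets(config)
    for name in config.set_shifts:
        if name not in gene_sets.sets:
            raise KeyError(f"set {name!r} not present in the gene-set collection")

    rng = np.random.default_rng(config.seed)
    proteins = np.array([f"P{i + 1:04d}" for i in range(config.n_proteins)])
    baseline = rng.lognormal(math.log(100.0), 1.0, size=config.n_proteins)

    fc = rng.normal(0.0, config.background_fc_sigma, size=config.n_proteins)
    shifted = np.zeros(config.n_proteins, dtype=bool)
    set_label = np.array([""] * config.n_proteins, dtype=object)
    for name, members in gene_sets.sets.items():
        mask = np.isin(proteins, list(members))
        set_label[mask] = name
        if name in config.set_shifts:
            fc[mask] += config.set_shifts[name]
            shifted |= mask

    n_pep = 1 + rng.poisson(config.peptides_per_protein_lambda,
                            size=config.n_proteins)
    prot_idx = np.repeat(np.arange(config.n_proteins), n_pep)
    pep_factor = rng.lognormal(0.0, 0.5, size=prot_idx.size)
    if config.balance_loading:
        # weight by realized total peptide signal so that noise-free channel
        # totals come out exactly equal (equal peptide loading per channel)
        signal = baseline * np.bincount(prot_idx, weights=pep_factor,
                                        minlength=config.n_proteins)
        fc[~shifted] += _loading_balance_offset(signal, fc, shifted)
    pep_names = [f"{proteins[p]}_pep{j + 1}"
                 for p, k in zip(range(config.n_proteins), n_pep)
                 for j in range(k)]

    n_ch = len(config.channels)
    channel_ids = [f"ch{i + 1}" for i in range(n_ch)]
    design = dict(zip(channel_ids, config.channels))
    treat = np.array([c == "treat" for c in config.channels], dtype=float)

    base = baseline[prot_idx] * pep_factor
    true_sn = base[:, None] * 10.0 ** (fc[prot_idx, None] * treat[None, :])
    if config.peptide_noise_cv > 0:
        sigma_ln = math.sqrt(math.log1p(config.peptide_noise_cv ** 2))
        true_sn = true_sn * rng.lognormal(-sigma_ln ** 2 / 2, sigma_ln,
                                          size=true_sn.shape)
    impurity = impurity_matrix_from_spillover(n_ch, config.impurity_spillover,
                                              channels=channel_ids)
    observed = true_sn @ impurity.to_numpy().T

    peptides = pd.DataFrame(observed, columns=channel_ids)
    peptides.insert(0, "protein", proteins[prot_idx])
    peptides.insert(0, "peptide", pep_names)

    truth = pd.DataFrame(
        {"log10_fc": fc, "set": set_label, "shifted": shifted,
         "baseline": baseline, "n_peptides": n_pep},
        index=pd.Index(proteins, name="protein"),
    )
    return TMTDataset(peptides=peptides, impurity=impurity, design=design,
                      truth=truth, config=config)


def expected_coverage(cells: float, moi: float, n_guides: int) -> float:
    """Expected selection-surviving cells per guide under Poisson infection.

    ``cells * (1 - exp(-moi)) / n_guides``: with multiplicity of infection
    ``moi``, a fraction ``1 - exp(-moi)`` of cells receives at least one
    lentiviral integrant and survives selection.
    """
    if n_guides <= 0:
        raise ValueError("n_guides must be positive")
    if cells < 0 or moi < 0:
        raise ValueError("cells and moi must be non-negative")
    return cells * (1.0 - math.exp(-moi)) / n_guides


def with_seed(config, seed: int):
    """Copy of a simulation config with a different seed."""
    return replace(config, seed=seed)
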