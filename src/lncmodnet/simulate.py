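"""Synthetic RNA-seq fixtures with planted co-expression structure.

The generator emulates a 24-sample drug-treatment experiment in a neuronal
cell model: four mood-stabiliser treatments (lamotrigine, quetiapine,
lithium, valproate), each with its matching vehicle (DMSO for the first two,
water for the last two) and four replicates per group.  Gene expression
follows a latent-factor model: each planted module m has a per-sample latent
eigengene u_m, drug-responsive modules receive an additive shift delta on
the drug arm of selected contrasts, and each member gene's log-expression is
``baseline + loading * u_m + noise``.  Counts are drawn Poisson (optionally
negative binomial) around library-size-scaled rates.

Everything is deterministic given the seed, and a machine-readable truth
object records modules, loadings, hubs, responsive contrasts, planted cis
pairs and planted TF-binding intervals so downstream recovery can be scored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DRUGS = ("lamotrigine", "quetiapine", "lithium", "valproate")
VEHICLES = ("DMSO", "water")

#: contrast name -> (drug group, vehicle group); names follow the common
#: vehicle_drug abbreviation (DMSO_LAM = lamotrigine vs DMSO, etc.)
CONTRASTS = {
    "DMSO_LAM": ("lamotrigine", "DMSO"),
    "DMSO_QUE": ("quetiapine", "DMSO"),
    "H2O_LIT": ("lithium", "water"),
    "H2O_VAL": ("valproate", "water"),
}


@dataclass(frozen=True)
class SampleDesign:
    """Sample sheet plus the drug-vehicle contrast map."""

    table: pd.DataFrame  # columns: sample, group, vehicle
    contrasts: Mapping[str, tuple[str, str]]

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    def group_samples(self, group: str) -> list[str]:
        sel = self.table[self.table["group"] == group]
        if sel.empty:
            raise KeyError(f"unknown group: {group}")
        return list(sel["sample"])

    def contrast_samples(self, contrast: str) -> tuple[list[str], list[str]]:
        """Return (drug samples, vehicle samples) for a contrast."""
        if contrast not in self.contrasts:
            raise KeyError(f"unknown contrast: {contrast}")
        drug, vehicle = self.contrasts[contrast]
        return self.group_samples(drug), self.group_samples(vehicle)

    def min_group_size(self) -> int:
        return int(self.table.groupby("group").size().min())


def generate_design(n_replicates: int = 4) -> SampleDesign:
    """Six treatment groups of ``n_replicates`` samples and four contrasts.

    Default layout: 4 samples x 2 vehicles plus 4 samples x 4 drug
    treatments = 24 samples, each drug contrasted against its own vehicle.
    """
    vehicle_of = {
        "DMSO": "DMSO",
        "water": "water",
        "lamotrigine": "DMSO",
        "quetiapine": "DMSO",
        "lithium": "water",
        "valproate": "water",
    }
    rows = []
    for group in list(VEHICLES) + list(DRUGS):
        for i in range(1, n_replicates + 1):
            rows.append(
                {"sample": f"{group}_{i}", "group": group, "vehicle": vehicle_of[group]}
            )
    return SampleDesign(table=pd.DataFrame(rows), contrasts=dict(CONTRASTS))


@dataclass(frozen=True)
class ResponsiveEffect:
    """Drug-induced shifts of a module eigengene.

    ``deltas`` maps contrast name -> shift on the latent (unit-variance)
    eigengene scale, added to the drug-arm samples of that contrast.
    Signs may differ between contrasts (an incoherent response).
    """

    deltas: Mapping[str, float]

    @classmethod
    def coherent(cls, contrasts, delta: float) -> "ResponsiveEffect":
        return cls({c: float(delta) for c in contrasts})

    @property
    def contrasts(self) -> tuple[str, ...]:
        return tuple(self.deltas)

    @property
    def coherent_sign(self) -> int:
        """+1/-1 when >= 3 shifts share one sign, else 0."""
        signs = {int(np.sign(d)) for d in self.deltas.values()}
        if len(signs) == 1 and len(self.deltas) >= 3:
            return signs.pop()
        return 0


@dataclass
class SimulationConfig:
    """Knobs of the planted-module generator.

    Defaults encode the study conditions exercised throughout the test
    suite: 5 modules of 60 genes on top of 700 background genes, loadings
    0.6-0.9 with a single 0.95-loading hub lncRNA per module, unit residual
    noise, and libraries of roughly ten million reads.  Every planted
    module responds to treatment in a distinct pattern — two coherently
    (same sign in >= 3 contrasts: the planted key modules), one in only
    two contrasts, and two with incoherent sign patterns — so each module
    has its own identifiable latent signature while the key-module rule
    still has genuine negatives.  ``delta`` magnitudes default to 6 latent
    standard deviations, chosen a priori so that a shifted eigengene is
    detectable at adjusted p < 0.05 in a 4 + 4 sample contrast with high
    per-contrast power.
    """

    module_sizes: tuple[int, ...] = (60, 60, 60, 60, 60)
    n_background_genes: int = 700
    lncRNA_fraction: float = 0.15
    responsive_modules: Mapping[int, ResponsiveEffect] = field(
        default_factory=lambda: {
            # the five patterns are chosen so that no module pair has a
            # positively correlated latent signature (anti-correlated pairs
            # are separable; positively correlated ones are not)
            # key: coherent positive response to all four drugs
            1: ResponsiveEffect.coherent(
                ("DMSO_LAM", "DMSO_QUE", "H2O_LIT", "H2O_VAL"), 6.0
            ),
            # key: coherent negative response to three drugs
            2: ResponsiveEffect.coherent(("DMSO_LAM", "DMSO_QUE", "H2O_LIT"), -6.0),
            # not key: only two (coherent) contrasts
            3: ResponsiveEffect.coherent(("DMSO_LAM", "H2O_VAL"), -6.0),
            # not key: three contrasts with mixed signs
            4: ResponsiveEffect(
                {"DMSO_LAM": 6.0, "H2O_LIT": -6.0, "H2O_VAL": -6.0}
            ),
            # not key: two contrasts with mixed signs
            5: ResponsiveEffect({"DMSO_QUE": -6.0, "H2O_LIT": 6.0}),
        }
    )
    hub_loading: float = 0.95
    loading_range: tuple[float, float] = (0.6, 0.9)
    noise_sd: float = 1.0
    #: weak sample-level covariation shared by all genes (library prep,
    #: culture batch...): each gene carries a small random loading on a few
    #: global latent factors.  This is what gives real RNA-seq its
    #: continuum of weak correlations and smoothly decaying connectivity;
    #: the sd is kept small enough that no sign-coherent global following
    #: reaches module size.
    n_global_factors: int = 5
    global_loading_sd: float = 0.25
    library_size_range: tuple[float, float] = (8e6, 12e6)
    dispersion: float | None = None  # None -> Poisson; else NB with this dispersion
    baseline_log_mean: float = np.log(100.0)
    baseline_log_sd: float = 1.0
    n_cis_pairs: int = 4
    n_tf_pairs: int = 3
    seed: int = 0

    def validate(self) -> None:
        if any(s < 30 for s in self.module_sizes):
            raise ValueError("every module size must be >= 30")
        if not (0.0 < self.lncRNA_fraction < 1.0):
            raise ValueError("lncRNA_fraction must be in (0, 1)")
        lo, hi = self.loading_range
        if not (0.0 < lo <= hi):
            raise ValueError("loading_range must be positive and ordered")
        if self.hub_loading <= hi:
            raise ValueError("hub_loading must exceed max(loading_range)")
        for m, eff in self.responsive_modules.items():
            if not (1 <= m <= len(self.module_sizes)):
                raise ValueError(f"responsive module {m} does not exist")
            if not eff.deltas:
                raise ValueError(f"module {m} listed responsive with no contrasts")
            for c, d in eff.deltas.items():
                if c not in CONTRASTS:
                    raise ValueError(f"unknown contrast {c!r} for module {m}")
                if d == 0:
                    raise ValueError(f"module {m} listed responsive with delta = 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth written alongside the synthetic data."""

    modules: dict[str, int]  # gene -> module (0 = background)
    loadings: dict[str, float]
    biotypes: dict[str, str]  # gene -> coding | lncRNA
    hubs: dict[int, str]  # module -> designated hub lncRNA
    responsive: dict[int, dict]  # module -> {contrasts, delta, sign}
    cis_pairs: list[dict] = field(default_factory=list)
    tf_pairs: list[dict] = field(default_factory=list)

    def module_genes(self, module: int) -> list[str]:
        return [g for g, m in self.modules.items() if m == module]

    @property
    def n_modules(self) -> int:
        return max(self.modules.values())

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["responsive"] = {str(k): v for k, v in payload["responsive"].items()}
        payload["hubs"] = {str(k): v for k, v in payload["hubs"].items()}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        payload["responsive"] = {int(k): v for k, v in payload["responsive"].items()}
        payload["hubs"] = {int(k): v for k, v in payload["hubs"].items()}
        return cls(**payload)


def _assign_genes(config: SimulationConfig, rng: np.random.Generator):
    """Fix gene ids, module membership, biotypes, hubs and loadings."""
    sizes = config.module_sizes
    n_genes = sum(sizes) + config.n_background_genes
    width = len(str(n_genes))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(n_genes)]

    modules: dict[str, int] = {}
    idx = 0
    for m, size in enumerate(sizes, start=1):
        for _ in range(size):
            modules[gene_ids[idx]] = m
            idx += 1
    for g in gene_ids[idx:]:
        modules[g] = 0

    # biotypes: designated hubs are lncRNAs; the rest sampled at the target
    # fraction over all genes.
    biotypes = {
        g: ("lncRNA" if rng.random() < config.lncRNA_fraction else "coding")
        for g in gene_ids
    }
    hubs: dict[int, str] = {}
    lo, hi = config.loading_range
    # non-hub lncRNAs draw from the lower third of the loading range:
    # lncRNAs are generally the more weakly expressed/connected species, and
    # the margin makes the designated hub the module's top-connectivity
    # lncRNA unambiguously at a 24-sample design
    lnc_hi = lo + (hi - lo) / 3.0
    loadings: dict[str, float] = {}
    for m, _ in enumerate(sizes, start=1):
        members = [g for g in gene_ids if modules[g] == m]
        hub = members[int(rng.integers(len(members)))]
        biotypes[hub] = "lncRNA"
        hubs[m] = hub
        for g in members:
            if g == hub:
                loadings[g] = config.hub_loading
            elif biotypes[g] == "lncRNA":
                loadings[g] = float(rng.uniform(lo, lnc_hi))
            else:
                loadings[g] = float(rng.uniform(lo, hi))
    for g in gene_ids:
        if modules[g] == 0:
            loadings[g] = 0.0
    return gene_ids, modules, biotypes, hubs, loadings


def _group_shifts(eff: ResponsiveEffect, design: SampleDesign) -> dict[str, float]:
    """Per-group latent shifts realizing the contrast deltas, centred.

    Within each vehicle family (the vehicle and its drugs) the vehicle
    level v is chosen to minimise the largest absolute group shift
    (v = -(max + min)/2 over the family's deltas including the vehicle's
    own zero), so the drug-minus-vehicle difference equals each contrast's
    delta exactly while every group's excursion stays within half the
    largest delta.  Bounding the excursions keeps count fold changes — and
    with them Poisson noise at the low end and library-composition
    distortion at the high end — in a realistic range instead of piling
    the whole shift onto the drug arm.
    """
    shifts: dict[str, float] = {}
    families: dict[str, list[str]] = {}
    for contrast, (drug, vehicle) in design.contrasts.items():
        families.setdefault(vehicle, []).append(contrast)
    for vehicle, contrasts in families.items():
        deltas = [eff.deltas.get(c, 0.0) for c in contrasts]
        v = -(max(deltas + [0.0]) + min(deltas + [0.0])) / 2.0
        shifts[vehicle] = v
        for c, d in zip(contrasts, deltas):
            drug = design.contrasts[c][0]
            shifts[drug] = v + d
    return shifts


def _latent_factors(
    config: SimulationConfig, design: SampleDesign, rng: np.random.Generator
) -> np.ndarray:
    """Per-module latent eigengenes (modules x samples), with drug shifts."""
    samples = design.samples
    n_modules = len(config.module_sizes)
    u = rng.standard_normal((n_modules, len(samples)))
    group_of = dict(zip(design.table["sample"], design.table["group"]))
    for m, eff in config.responsive_modules.items():
        shifts = _group_shifts(eff, design)
        for j, s in enumerate(samples):
            u[m - 1, j] += shifts.get(group_of[s], 0.0)
    return u


def _draw_counts(
    rates: np.ndarray,
    lib_sizes: np.ndarray,
    dispersion: float | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Counts ~ Poisson (or NB) around library-scaled relative abundances."""
    probs = rates / rates.sum(axis=0, keepdims=True)
    mu = probs * lib_sizes[np.newaxis, :]
    if dispersion is None:
        return rng.poisson(mu)
    # NB parameterised by mean mu and dispersion phi: var = mu + phi * mu^2
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _counts_frame(
    config: SimulationConfig,
    design: SampleDesign,
    gene_ids: Sequence[str],
    modules: Mapping[str, int],
    loadings: Mapping[str, float],
    baselines: np.ndarray,
    global_loadings: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    u = _latent_factors(config, design, rng)
    load = np.array([loadings[g] for g in gene_ids])
    mod = np.array([modules[g] for g in gene_ids])
    signal = np.zeros((len(gene_ids), len(design.samples)))
    in_module = mod > 0
    signal[in_module] = load[in_module, None] * u[mod[in_module] - 1]
    if config.n_global_factors:
        w = rng.standard_normal((config.n_global_factors, len(design.samples)))
        signal += global_loadings @ w
    noise = rng.normal(0.0, config.noise_sd, size=signal.shape)
    log_expr = baselines[:, None] + signal + noise
    lib_sizes = rng.uniform(*config.library_size_range, size=len(design.samples))
    counts = _draw_counts(np.exp(log_expr), lib_sizes, config.dispersion, rng)
    return pd.DataFrame(counts, index=list(gene_ids), columns=design.samples)


def simulate_dataset(
    config: SimulationConfig, design: SampleDesign
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw the primary count matrix and its ground truth.

    Returns a (genes x samples) integer DataFrame and a
    :class:`SyntheticTruth` whose per-gene baselines/loadings also seed
    :func:`simulate_replicate`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_ids, modules, biotypes, hubs, loadings = _assign_genes(config, rng)
    baselines = rng.normal(
        config.baseline_log_mean, config.baseline_log_sd, size=len(gene_ids)
    )
    global_loadings = rng.normal(
        0.0, config.global_loading_sd, size=(len(gene_ids), config.n_global_factors)
    )
    counts = _counts_frame(
        config, design, gene_ids, modules, loadings, baselines, global_loadings, rng
    )
    truth = SyntheticTruth(
        modules=modules,
        loadings={g: float(loadings[g]) for g in gene_ids},
        biotypes=biotypes,
        hubs=hubs,
        responsive={
            m: {
                "contrasts": list(eff.contrasts),
                "deltas": {c: float(d) for c, d in eff.deltas.items()},
                "coherent_sign": eff.coherent_sign,
            }
            for m, eff in config.responsive_modules.items()
        },
    )
    # baselines and global-factor loadings are not part of the public truth
    # contract but are needed to draw replicates sharing the same structure
    truth._baselines = {g: float(b) for g, b in zip(gene_ids, baselines)}  # type: ignore[attr-defined]
    truth._global_loadings = global_loadings  # type: ignore[attr-defined]
    truth._config = config  # type: ignore[attr-defined]
    return counts, truth


def simulate_replicate(
    truth: SyntheticTruth,
    design: SampleDesign,
    seed: int,
    scramble_module: int | None = None,
) -> pd.DataFrame:
    """Independent dataset sharing the truth's module structure.

    New latent factors, noise and library sizes are drawn under ``seed``;
    gene ids, module assignments, loadings and baselines are carried over,
    so genuinely co-expressed modules reproduce while everything else is
    fresh.  ``scramble_module`` enables a negative control: the loading/
    factor assignments of that module's genes are permuted jointly with the
    background genes, so the module's original members lose their shared
    factor in the replicate and should not test as preserved.
    """
    config: SimulationConfig = getattr(truth, "_config", None)
    baselines_map = getattr(truth, "_baselines", None)
    if config is None or baselines_map is None:
        raise ValueError("truth must come from simulate_dataset")
    rng = np.random.default_rng(seed)
    gene_ids = list(truth.modules)
    modules = dict(truth.modules)
    loadings = dict(truth.loadings)
    if scramble_module is not None:
        pool = [
            g
            for g in gene_ids
            if modules[g] == scramble_module or modules[g] == 0
        ]
        perm = list(rng.permutation(len(pool)))
        new_assign = {
            pool[i]: (modules[pool[j]], loadings[pool[j]])
            for i, j in enumerate(perm)
        }
        for g, (m, l) in new_assign.items():
            modules[g], loadings[g] = m, l
    baselines = np.array([baselines_map[g] for g in gene_ids])
    global_loadings = getattr(truth, "_global_loadings")
    return _counts_frame(
        config, design, gene_ids, modules, loadings, baselines, global_loadings, rng
    )


# ---------------------------------------------------------------------------
# toy genome annotation and TF binding intervals
# ---------------------------------------------------------------------------

GENE_LENGTH = 1_000
TSS_SPACING = 250_000  # grid spacing between placement units; > cis window
CHROMS = ("chrA", "chrB", "chrC")
PROMOTER_UPSTREAM = 30_000
PROMOTER_DOWNSTREAM = 10_000
CIS_WINDOW = 100_000
#: planted |TSS distance| values; includes the exact 100 kb boundary
CIS_DISTANCES = (50_000, 100_000, 80_000, 20_000, 60_000, 40_000, 90_000, 30_000)


def _gene_interval(tss: int, strand: str) -> tuple[int, int]:
    """0-based half-open gene body with TSS = start (+) or end-1 (-)."""
    if strand == "+":
        return tss, tss + GENE_LENGTH
    return tss - GENE_LENGTH + 1, tss + 1


def generate_annotation(
    truth: SyntheticTruth, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Toy-genome coordinates plus a TF-binding interval table.

    Genes are laid out on a 250 kb TSS grid over three chromosomes, so no
    gene pair is within the 100 kb cis window unless planted.  Planted cis
    pairs (same-module lncRNA/coding pairs, one at exactly 100 kb) and
    planted TF intervals (inside the strand-aware -30/+10 kb promoter
    window of a same-module lncRNA, with decoys outside and one abutting
    the half-open window edge) are recorded in the truth object.
    """
    rng = np.random.default_rng(seed)
    config: SimulationConfig = getattr(truth, "_config", None)
    n_cis = config.n_cis_pairs if config is not None else 4
    n_tf = config.n_tf_pairs if config is not None else 3

    # choose planted cis pairs: lncRNA + coding gene from the same module
    cis_pairs: list[tuple[str, str, int]] = []
    used: set[str] = set()
    modules_cycle = list(range(1, truth.n_modules + 1))
    d_iter = iter(CIS_DISTANCES)
    while len(cis_pairs) < n_cis and modules_cycle:
        m = modules_cycle[len(cis_pairs) % len(modules_cycle)]
        members = truth.module_genes(m)
        lncs = [g for g in members if truth.biotypes[g] == "lncRNA" and g not in used]
        cods = [g for g in members if truth.biotypes[g] == "coding" and g not in used]
        if not lncs or not cods:
            break
        lnc = lncs[int(rng.integers(len(lncs)))]
        cod = cods[int(rng.integers(len(cods)))]
        used.update((lnc, cod))
        cis_pairs.append((lnc, cod, next(d_iter)))

    # placement units: cis pairs occupy one unit (two genes at a fixed TSS
    # offset); everything else is a singleton
    paired = {g for pair in cis_pairs for g in pair[:2]}
    singles = [g for g in truth.modules if g not in paired]
    units: list[tuple] = [("pair", *p) for p in cis_pairs] + [
        ("single", g) for g in singles
    ]
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    rows = []
    per_chrom = int(np.ceil(len(units) / len(CHROMS)))
    for u_idx, unit in enumerate(units):
        chrom = CHROMS[u_idx // per_chrom]
        slot = u_idx % per_chrom
        base_tss = 1_000_000 + slot * TSS_SPACING
        if unit[0] == "single":
            g = unit[1]
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = _gene_interval(base_tss, strand)
            rows.append((g, chrom, start, end, strand))
        else:
            _, lnc, cod, dist = unit
            for g, tss in ((lnc, base_tss), (cod, base_tss + dist)):
                strand = "+" if rng.random() < 0.5 else "-"
                start, end = _gene_interval(tss, strand)
                rows.append((g, chrom, start, end, strand))
    annotation = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    annotation["biotype"] = annotation["gene_id"].map(truth.biotypes)
    annotation = annotation[
        ["gene_id", "biotype", "chrom", "start", "end", "strand"]
    ].reset_index(drop=True)

    truth.cis_pairs = [
        {"lncRNA": lnc, "coding": cod, "tss_distance": int(d)}
        for lnc, cod, d in cis_pairs
    ]

    # planted TF regulation: a coding gene of the same module binds inside
    # the lncRNA's promoter window
    ann_ix = annotation.set_index("gene_id")

    def _tss(g: str) -> int:
        row = ann_ix.loc[g]
        return int(row["start"] if row["strand"] == "+" else row["end"] - 1)

    def _promoter(g: str) -> tuple[str, int, int]:
        row = ann_ix.loc[g]
        t = _tss(g)
        if row["strand"] == "+":
            lo, hi = t - PROMOTER_UPSTREAM, t + PROMOTER_DOWNSTREAM
        else:
            lo, hi = t - PROMOTER_DOWNSTREAM + 1, t + PROMOTER_UPSTREAM + 1
        return str(row["chrom"]), max(lo, 0), hi

    tf_rows = []
    tf_pairs = []
    cis_genes = used
    for m in range(1, truth.n_modules + 1):
        if len(tf_pairs) >= n_tf:
            break
        members = truth.module_genes(m)
        lncs = [
            g
            for g in members
            if truth.biotypes[g] == "lncRNA" and g not in cis_genes
        ]
        tfs = [
            g
            for g in members
            if truth.biotypes[g] == "coding" and g not in cis_genes
        ]
        if not lncs or not tfs:
            continue
        lnc = lncs[int(rng.integers(len(lncs)))]
        tf = tfs[int(rng.integers(len(tfs)))]
        chrom, lo, hi = _promoter(lnc)
        mid = (lo + hi) // 2
        interval = (mid - 250, mid + 250)
        tf_rows.append((chrom, *interval, tf))
        # decoys for the same TF: outside the window, one abutting its edge
        tf_rows.append((chrom, max(lo - 5_000, 0), max(lo - 4_500, 1), tf))
        tf_rows.append((chrom, max(lo - 500, 0), lo, tf))  # end == window start
        tf_pairs.append(
            {
                "tf": tf,
                "lncRNA": lnc,
                "interval": [chrom, int(interval[0]), int(interval[1])],
            }
        )
    truth.tf_pairs = tf_pairs
    tf_binding = pd.DataFrame(
        tf_rows, columns=["chrom", "start", "end", "tf_gene_id"]
    )
    return annotation, tf_binding


def generate_gene_sets(truth: SyntheticTruth, seed: int) -> dict[str, list[str]]:
    """GMT-writable gene sets with planted enrichment structure.

    Per planted module: one set equal to the module (maximal-overlap
    positive) and one partially overlapping set sharing a name token with
    it (drives an enrichment-map edge).  Plus size-matched random negative
    sets, and a detached pair of 4-gene sets with 2 shared members, whose
    combined Jaccard/overlap coefficient is 5/12 ~ 0.4167.
    """
    rng = np.random.default_rng(seed)
    universe = list(truth.modules)
    themes = ("VESICLE", "CHROMATIN", "ER_STRESS", "NEURODEV", "MATRIX")
    sets: dict[str, list[str]] = {}
    for m in range(1, truth.n_modules + 1):
        theme = themes[(m - 1) % len(themes)]
        members = truth.module_genes(m)
        sets[f"{theme}_CORE_M{m}"] = sorted(members)
        # sibling set: half the module plus random outside genes
        half = sorted(members)[: len(members) // 2]
        extra = [g for g in universe if truth.modules[g] != m]
        pad = [extra[i] for i in rng.choice(len(extra), size=len(half), replace=False)]
        sets[f"{theme}_SIB_M{m}"] = sorted(half + pad)
    for i in range(10):
        size = 60
        pick = rng.choice(len(universe), size=size, replace=False)
        sets[f"RANDOM_NULL_{i + 1}"] = sorted(universe[j] for j in pick)
    # detached worked-coefficient pair: |A|=|B|=4, |A and B|=2
    background = [g for g in universe if truth.modules[g] == 0]
    six = [background[i] for i in rng.choice(len(background), size=6, replace=False)]
    sets["TOYPAIR_A"] = sorted(six[:4])
    sets["TOYPAIR_B"] = sorted(six[2:])
    return sets


# ---------------------------------------------------------------------------
# writers (plain-text External Interfaces)
# ---------------------------------------------------------------------------


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            members = "\t".join(sets[name])
            fh.write(f"{name}\tsynthetic\t{members}\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, _desc, *members = line.split("\t")
        sets[name] = members
    return sets


def write_fixture(
    out_dir: str | Path,
    config: SimulationConfig | None = None,
    replicate_seed_offset: int = 1,
) -> Path:
    """Generate and write the full fixture bundle under ``out_dir``.

    Writes counts.tsv, counts_replicate.tsv, design.tsv, annotation.tsv,
    tf_binding.bed, genesets.gmt and truth.json.
    """
    config = config or SimulationConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = generate_design()
    counts, truth = simulate_dataset(config, design)
    replicate = simulate_replicate(truth, design, config.seed + replicate_seed_offset)
    annotation, tf_binding = generate_annotation(truth, config.seed + 2)
    sets = generate_gene_sets(truth, config.seed + 3)

    counts.rename_axis("gene_id").to_csv(out / "counts.tsv", sep="\t")
    replicate.rename_axis("gene_id").to_csv(out / "counts_replicate.tsv", sep="\t")
    design.table.assign(
        contrast=design.table["group"].map(
            {drug: name for name, (drug, _v) in CONTRASTS.items()}
        )
    ).to_csv(out / "design.tsv", sep="\t", index=False)
    annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
    tf_binding.to_csv(out / "tf_binding.bed", sep="\t", index=False, header=False)
    write_gmt(sets, out / "genesets.gmt")
    truth.to_json(out / "truth.json")
    return out
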