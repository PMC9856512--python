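"""Synthetic multi-omics data with planted ground truth.

Every generator in this module emulates one input of the resistance
pipeline — paired M.SssI/no-enzyme methylation-array β matrices, RNA count
matrices, per-sample somatic variant tables, BH3-profiling TMRE readouts
and dose-response viability curves — and returns, alongside the data, a
:class:`SimulationTruth` recording exactly which entities carry a planted
effect.  Downstream stages are tested by recovering that truth.

The epigenome generator inverts the accessibility model used by the
analysis: accessibility is the β gain of the methyltransferase-treated arm
over the untreated arm, so a probe planted "accessibility up" in the
affected condition has its treated-arm β raised by ``planted_delta`` while
the untreated arm is left alone, and a probe planted "methylation up" has
both arms raised so the accessibility difference stays zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError

AUTOSOMES = [f"chr{i}" for i in range(1, 23)]
SEX_CHROMS = ["chrX", "chrY"]

#: BH3 peptide panel with the concentrations (µM) used in the profiling assay.
DEFAULT_BH3_PANEL: tuple[tuple[str, float], ...] = (
    ("BIM", 0.5),
    ("BIM", 1.0),
    ("PUMA", 10.0),
    ("PUMA2a", 10.0),
    ("BAD", 2.0),
    ("BAD", 10.0),
    ("NOXA", 100.0),
    ("wHRK", 100.0),
    ("MS1", 20.0),
    ("FS1", 10.0),
)

BH3_PEPTIDES = frozenset(p for p, _ in DEFAULT_BH3_PANEL)


# ---------------------------------------------------------------------------
# truth container
# ---------------------------------------------------------------------------


@dataclass
class SimulationTruth:
    """Planted-effect labels for every simulated entity.

    Only the fields relevant to the generator that produced the truth are
    populated; all tables are indexed by the entity identifier used in the
    corresponding data tables so recovery tests can join on it.
    """

    probes: pd.DataFrame | None = None
    genes: pd.DataFrame | None = None
    variants: pd.DataFrame | None = None
    bh3: pd.DataFrame | None = None

    def to_json(self) -> str:
        payload = {}
        for name in ("probes", "genes", "variants", "bh3"):
            df = getattr(self, name)
            if df is not None:
                payload[name] = json.loads(df.to_json(orient="table"))
        return json.dumps(payload, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


# ---------------------------------------------------------------------------
# epigenome (paired SssI / NoE β matrices)
# ---------------------------------------------------------------------------


@dataclass
class EpiSimConfig:
    """Configuration of the paired-arm methylation-array simulator.

    ``groups`` maps condition labels to replicate counts; the condition
    named ``affected_group`` carries every planted effect, all others share
    the baseline epigenome (mimicking parental and long-term-cultured lines
    whose profiles stay close to each other).
    """

    n_probes: int = 10_000
    n_promoter_genes: int = 500
    probes_per_promoter: int = 2
    groups: Mapping[str, int] = field(
        default_factory=lambda: {"sensitive": 3, "resistant": 3}
    )
    affected_group: str = "resistant"
    frac_snp: float = 0.0
    frac_crossreactive: float = 0.0
    frac_sex_chrom: float = 0.0
    frac_sig_acc_up: float = 0.0
    frac_sig_acc_down: float = 0.0
    frac_sig_meth_up: float = 0.0
    frac_sig_meth_down: float = 0.0
    planted_delta: float = 0.3
    beta_noise_sd: float = 0.02
    detection_fail_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        props = {
            "frac_snp": self.frac_snp,
            "frac_crossreactive": self.frac_crossreactive,
            "frac_sex_chrom": self.frac_sex_chrom,
            "frac_sig_acc_up": self.frac_sig_acc_up,
            "frac_sig_acc_down": self.frac_sig_acc_down,
            "frac_sig_meth_up": self.frac_sig_meth_up,
            "frac_sig_meth_down": self.frac_sig_meth_down,
            "detection_fail_rate": self.detection_fail_rate,
        }
        for name, value in props.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        sig_total = (
            self.frac_sig_acc_up
            + self.frac_sig_acc_down
            + self.frac_sig_meth_up
            + self.frac_sig_meth_down
        )
        if sig_total > 1.0:
            raise ConfigError(f"significant-probe fractions sum to {sig_total} > 1")
        if self.planted_delta <= 0:
            raise ConfigError("planted_delta must be positive")
        if self.beta_noise_sd < 0:
            raise ConfigError("beta_noise_sd must be non-negative")
        if self.n_probes <= 0:
            raise ConfigError("n_probes must be positive")
        if self.affected_group not in self.groups:
            raise ConfigError(
                f"affected_group {self.affected_group!r} not among groups"
            )
        if any(n < 1 for n in self.groups.values()):
            raise ConfigError("every group needs at least one replicate")
        if self.n_promoter_genes * self.probes_per_promoter > self.n_probes:
            raise ConfigError("promoter probes exceed n_probes")


@dataclass
class EpigenomeData:
    """Paired β matrices plus manifest, detection p-values and truth."""

    manifest: pd.DataFrame
    beta_sssi: pd.DataFrame
    beta_noe: pd.DataFrame
    detection: pd.DataFrame
    truth: SimulationTruth

    @property
    def samples(self) -> list[str]:
        return list(self.beta_sssi.columns)


def _sample_names(groups: Mapping[str, int]) -> list[str]:
    return [f"{label}_{i + 1}" for label, n in groups.items() for i in range(n)]


def simulate_epigenome(
    cfg: EpiSimConfig,
    promoter_plan: Mapping[str, str] | None = None,
) -> EpigenomeData:
    """Generate paired SssI/NoE β matrices with planted differentials.

    ``promoter_plan`` optionally maps gene symbols to a planted promoter
    direction (``"up"``: accessibility gain + methylation loss in the
    affected group; ``"down"``: the mirror image; ``"none"``: promoter
    probes with no planted change).  Plan genes are assigned promoter
    probes first, ahead of the config's generic promoter genes, and their
    probes are kept free of exclusion flags so the planted signal survives
    QC.  Probes flagged as SNP-overlapping, cross-reactive or
    sex-chromosomal never carry planted signal.
    """
    cfg.validate()
    promoter_plan = dict(promoter_plan or {})
    bad = {d for d in promoter_plan.values()} - {"up", "down", "none"}
    if bad:
        raise ConfigError(f"promoter_plan directions must be up/down/none, got {bad}")

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_probes
    ppp = cfg.probes_per_promoter
    n_prom_genes = max(cfg.n_promoter_genes, len(promoter_plan))
    if n_prom_genes * ppp > n:
        raise ConfigError("promoter plan does not fit within n_probes")

    probe_ids = np.array([f"cg{i:08d}" for i in range(n)])

    # gene assignment: plan genes first, then filler promoter genes
    plan_genes = sorted(promoter_plan)
    filler = [f"gene_{i:05d}" for i in range(n_prom_genes)]
    filler = [g for g in filler if g not in promoter_plan][: n_prom_genes - len(plan_genes)]
    prom_genes = plan_genes + filler
    gene_col = np.array([""] * n, dtype=object)
    promoter_col = np.zeros(n, dtype=bool)
    n_prom_probes = len(prom_genes) * ppp
    gene_col[:n_prom_probes] = np.repeat(prom_genes, ppp)
    promoter_col[:n_prom_probes] = True

    # exclusion flags; planned promoter probes stay clean
    snp = rng.random(n) < cfg.frac_snp
    xreact = rng.random(n) < cfg.frac_crossreactive
    sex = rng.random(n) < cfg.frac_sex_chrom
    planned = np.zeros(n, dtype=bool)
    planned[: len(plan_genes) * ppp] = True
    snp[planned] = False
    xreact[planned] = False
    sex[planned] = False

    chrom = rng.choice(AUTOSOMES, size=n)
    chrom[sex] = rng.choice(SEX_CHROMS, size=int(sex.sum()))

    manifest = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": chrom,
            "gene": gene_col,
            "promoter_region": promoter_col,
            "snp_flag": snp,
            "crossreactive_flag": xreact,
        }
    ).set_index("probe_id")

    # planted per-probe effects (β scale, affected group only)
    d_acc = np.zeros(n)
    d_meth = np.zeros(n)
    delta = cfg.planted_delta
    for gi, gene in enumerate(plan_genes):
        sl = slice(gi * ppp, (gi + 1) * ppp)
        direction = promoter_plan[gene]
        if direction == "up":
            d_acc[sl] = delta
            d_meth[sl] = -delta
        elif direction == "down":
            d_acc[sl] = -delta
            d_meth[sl] = delta

    clean = ~(snp | xreact | sex) & ~planned
    pool = np.flatnonzero(clean)
    rng.shuffle(pool)
    counts = [
        int(round(cfg.frac_sig_acc_up * n)),
        int(round(cfg.frac_sig_acc_down * n)),
        int(round(cfg.frac_sig_meth_up * n)),
        int(round(cfg.frac_sig_meth_down * n)),
    ]
    if sum(counts) > pool.size:
        raise ConfigError("not enough clean probes for the requested fractions")
    offset = 0
    for count, (da, dm) in zip(counts, [(delta, 0.0), (-delta, 0.0), (0.0, delta), (0.0, -delta)]):
        idx = pool[offset : offset + count]
        d_acc[idx] = da
        d_meth[idx] = dm
        offset += count

    # baseline epigenome chosen so planted shifts stay inside [0, 1]
    base_meth = rng.uniform(0.35, 0.55, size=n)
    base_acc = rng.uniform(0.0, 0.08, size=n)

    samples = _sample_names(cfg.groups)
    affected = np.array(
        [s.rsplit("_", 1)[0] == cfg.affected_group for s in samples]
    )
    noe = base_meth[:, None] + np.where(affected, d_meth[:, None], 0.0)
    sssi = noe + base_acc[:, None] + np.where(affected, d_acc[:, None], 0.0)
    if cfg.beta_noise_sd > 0:
        noe = noe + rng.normal(0.0, cfg.beta_noise_sd, size=noe.shape)
        sssi = sssi + rng.normal(0.0, cfg.beta_noise_sd, size=sssi.shape)
    noe = np.clip(noe, 0.0, 1.0)
    sssi = np.clip(sssi, 0.0, 1.0)

    beta_noe = pd.DataFrame(noe, index=manifest.index, columns=samples)
    beta_sssi = pd.DataFrame(sssi, index=manifest.index, columns=samples)

    detection = pd.DataFrame(
        rng.uniform(0.0, 0.009, size=(n, len(samples))),
        index=manifest.index,
        columns=samples,
    )
    if cfg.detection_fail_rate > 0:
        fail = rng.random(detection.shape) < cfg.detection_fail_rate
        detection = detection.mask(
            fail, rng.uniform(0.011, 0.5, size=detection.shape)
        )

    direction = np.where(
        (d_acc > 0) | (d_meth < 0), "up", np.where((d_acc < 0) | (d_meth > 0), "down", "none")
    )
    truth_probes = pd.DataFrame(
        {
            "planted_delta_acc": d_acc,
            "planted_delta_meth": d_meth,
            "planted_direction": direction,
            "gene": gene_col,
        },
        index=manifest.index,
    )
    return EpigenomeData(
        manifest=manifest,
        beta_sssi=beta_sssi,
        beta_noe=beta_noe,
        detection=detection,
        truth=SimulationTruth(probes=truth_probes),
    )


# ---------------------------------------------------------------------------
# RNA counts
# ---------------------------------------------------------------------------


@dataclass
class RnaSimConfig:
    """Two-group negative-binomial count simulator with planted DE genes."""

    n_genes: int = 20_000
    n_up: int = 0
    n_down: int = 0
    lfc_magnitude: float = 3.0
    dispersion: float = 0.05
    baseline_mean: float = 100.0
    replicates_per_group: int = 3
    group_labels: tuple[str, str] = ("parental", "resistant")
    concordance_up: float = 0.0
    concordance_down: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_up + self.n_down > self.n_genes:
            raise ConfigError("n_up + n_down exceeds n_genes")
        if self.n_up < 0 or self.n_down < 0:
            raise ConfigError("planted counts must be non-negative")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean must be positive")
        if self.replicates_per_group < 1:
            raise ConfigError("need at least one replicate per group")
        for name in ("concordance_up", "concordance_down"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")


@dataclass
class RnaData:
    counts: pd.DataFrame
    groups: pd.Series  # sample -> group label
    truth: SimulationTruth


def simulate_counts(cfg: RnaSimConfig) -> RnaData:
    """Generate NB counts where planted genes shift the second group's mean
    by exactly ``2**±lfc_magnitude`` relative to the first group.

    The truth table additionally flags, per planted DE gene, whether the
    gene is to receive a concordant promoter-level epigenetic change (an
    exact ``round(concordance * n_planted)`` of each direction), which the
    epigenome generator consumes as a promoter plan.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = np.array([f"gene_{i:05d}" for i in range(cfg.n_genes)])

    order = rng.permutation(cfg.n_genes)
    up_idx = order[: cfg.n_up]
    down_idx = order[cfg.n_up : cfg.n_up + cfg.n_down]
    de_direction = np.array(["none"] * cfg.n_genes, dtype=object)
    de_direction[up_idx] = "up"
    de_direction[down_idx] = "down"

    concordant = np.zeros(cfg.n_genes, dtype=bool)
    concordant[up_idx[: int(round(cfg.concordance_up * cfg.n_up))]] = True
    concordant[down_idx[: int(round(cfg.concordance_down * cfg.n_down))]] = True

    fold = np.ones(cfg.n_genes)
    fold[up_idx] = 2.0**cfg.lfc_magnitude
    fold[down_idx] = 2.0**-cfg.lfc_magnitude

    nrep = cfg.replicates_per_group
    labels = [cfg.group_labels[0]] * nrep + [cfg.group_labels[1]] * nrep
    samples = [f"{lab}_{i % nrep + 1}" for i, lab in enumerate(labels)]
    mu = np.empty((cfg.n_genes, 2 * nrep))
    mu[:, :nrep] = cfg.baseline_mean
    mu[:, nrep:] = cfg.baseline_mean * fold[:, None]

    counts = _nb_draw(rng, mu, cfg.dispersion)
    truth_genes = pd.DataFrame(
        {"de_direction": de_direction, "concordant_promoter": concordant},
        index=pd.Index(genes, name="gene"),
    )
    return RnaData(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples),
        groups=pd.Series(labels, index=samples, name="group"),
        truth=SimulationTruth(genes=truth_genes),
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    # NB parameterized by mean and dispersion alpha: var = mu + alpha mu^2.
    # alpha -> 0 degenerates to Poisson.
    if dispersion < 1e-12:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def promoter_plan_from_truth(truth: SimulationTruth) -> dict[str, str]:
    """Promoter directions for the epigenome generator: concordant DE genes
    get a promoter change matching their expression direction; the other DE
    genes get signal-free promoter probes so they still enter promoter
    classification."""
    if truth.genes is None:
        raise ConfigError("truth carries no gene table")
    plan: dict[str, str] = {}
    for gene, row in truth.genes.iterrows():
        if row["de_direction"] == "none":
            continue
        plan[str(gene)] = row["de_direction"] if row["concordant_promoter"] else "none"
    return plan


# ---------------------------------------------------------------------------
# somatic variants
# ---------------------------------------------------------------------------

IMPACT_LEVELS = ("HIGH", "MODERATE", "LOW", "MODIFIER")

#: sample labels emitted by the variant simulator, per resistant line a/b
VARIANT_SAMPLES = (
    "parental_a",
    "longterm_a",
    "vr_a",
    "parental_b",
    "longterm_b",
    "vr_b",
)


@dataclass
class VariantSimConfig:
    """Planted variant classes for the acquired-variant filter cascade.

    * ``n_background`` — present in the parental/long-term controls (and the
      resistant samples); half are rare + HIGH impact so that only the
      background subtraction removes them.
    * ``n_private_fail_af`` — resistant-only but common (gnomAD ≥ 0.001).
    * ``n_private_fail_impact`` — resistant-only, rare, but below HIGH impact.
    * ``n_shared_pass`` — survive every filter in both resistant samples.
    * ``n_private_pass_each`` — survive every filter but in one resistant
      sample only.
    """

    n_background: int = 0
    n_private_fail_af: int = 0
    n_private_fail_impact: int = 0
    n_shared_pass: int = 0
    n_private_pass_each: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_background",
            "n_private_fail_af",
            "n_private_fail_impact",
            "n_shared_pass",
            "n_private_pass_each",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass
class VariantData:
    #: sample label -> variant table (chromosome, position, ref, alt,
    #: gnomad_af [NaN = absent], impact [None = absent])
    tables: dict[str, pd.DataFrame]
    truth: SimulationTruth


_BASES = np.array(list("ACGT"))


def _random_variants(rng: np.random.Generator, n: int, positions: np.ndarray) -> pd.DataFrame:
    chrom = rng.choice(AUTOSOMES, size=n)
    ref = rng.choice(_BASES, size=n)
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    return pd.DataFrame(
        {"chromosome": chrom, "position": positions, "ref": ref, "alt": alt}
    )


def simulate_variants(cfg: VariantSimConfig) -> VariantData:
    """Emit per-sample variant tables planting each cascade outcome class."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    total = (
        cfg.n_background
        + cfg.n_private_fail_af
        + cfg.n_private_fail_impact
        + 2 * cfg.n_private_pass_each
        + cfg.n_shared_pass
    )
    positions = rng.choice(np.arange(10_000, 50_000_000), size=total, replace=False)
    base = _random_variants(rng, total, positions)

    classes = (
        ["background"] * cfg.n_background
        + ["fail_af"] * cfg.n_private_fail_af
        + ["fail_impact"] * cfg.n_private_fail_impact
        + ["shared_pass"] * cfg.n_shared_pass
        + ["private_pass_a"] * cfg.n_private_pass_each
        + ["private_pass_b"] * cfg.n_private_pass_each
    )
    base["planted_class"] = classes

    af = np.full(total, np.nan)
    impact = np.empty(total, dtype=object)
    for i, cls in enumerate(classes):
        if cls == "fail_af":
            af[i] = rng.uniform(0.001, 0.05)
            impact[i] = "HIGH"
        elif cls == "fail_impact":
            af[i] = rng.uniform(0.0, 0.0009)
            impact[i] = rng.choice(["MODERATE", "LOW", "MODIFIER", None])
        elif cls == "background":
            # half of the background would pass AF+impact: the subtraction
            # has to be what removes them
            if rng.random() < 0.5:
                af[i] = rng.uniform(0.0, 0.0009)
                impact[i] = "HIGH"
            else:
                af[i] = rng.uniform(0.0, 0.05)
                impact[i] = rng.choice(IMPACT_LEVELS)
        else:  # passing classes: rare (or unseen in gnomAD) and HIGH
            af[i] = rng.uniform(0.0, 0.0009) if rng.random() < 0.7 else np.nan
            impact[i] = "HIGH"
    base["gnomad_af"] = af
    base["impact"] = impact

    cls_s = base["planted_class"]
    membership = {
        "parental_a": cls_s.eq("background"),
        "longterm_a": cls_s.eq("background"),
        "parental_b": cls_s.eq("background"),
        "longterm_b": cls_s.eq("background"),
        "vr_a": cls_s.isin(["background", "fail_af", "fail_impact", "shared_pass", "private_pass_a"]),
        "vr_b": cls_s.isin(["background", "fail_af", "fail_impact", "shared_pass", "private_pass_b"]),
    }
    cols = ["chromosome", "position", "ref", "alt", "gnomad_af", "impact"]
    tables = {
        sample: base.loc[mask, cols].sort_values(["chromosome", "position"]).reset_index(drop=True)
        for sample, mask in membership.items()
    }
    truth = base[["chromosome", "position", "ref", "alt", "planted_class"]].copy()
    return VariantData(tables=tables, truth=SimulationTruth(variants=truth))


# ---------------------------------------------------------------------------
# BH3 profiling readouts
# ---------------------------------------------------------------------------


@dataclass
class Bh3SimConfig:
    """TMRE readout simulator for the BH3 peptide panel.

    ``true_depolarization`` maps condition label -> {(peptide, µM): fraction
    in [0, 1]}.  The noise-free readout follows the two-control linear
    model ``signal = dmso - f * (dmso - fccp)``: full depolarization drops
    the signal to the FCCP (positive-control) level, none leaves it at the
    DMSO (vehicle) level.
    """

    true_depolarization: Mapping[str, Mapping[tuple[str, float], float]] = field(
        default_factory=dict
    )
    panel: Sequence[tuple[str, float]] = DEFAULT_BH3_PANEL
    dmso_level: float = 1000.0
    fccp_level: float = 100.0
    noise_sd: float = 0.0
    replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.fccp_level >= self.dmso_level:
            raise ConfigError(
                "FCCP (full depolarization) signal must lie below the DMSO level"
            )
        for cond, peps in self.true_depolarization.items():
            for key, f in peps.items():
                if not 0.0 <= f <= 1.0:
                    raise ConfigError(
                        f"true depolarization {f} for {cond}/{key} outside [0, 1]"
                    )
        for pep, conc in self.panel:
            if conc <= 0:
                raise ConfigError(f"peptide {pep} concentration must be positive")
        if self.replicates < 1:
            raise ConfigError("need at least one replicate")


@dataclass
class Bh3Data:
    #: long table: condition, peptide, concentration_um, replicate, tmre_signal
    #: (controls appear as peptides "DMSO" and "FCCP", concentration NaN)
    measurements: pd.DataFrame
    truth: SimulationTruth


def simulate_bh3(cfg: Bh3SimConfig) -> Bh3Data:
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    truth_rows = []
    span = cfg.dmso_level - cfg.fccp_level
    for cond, peps in cfg.true_depolarization.items():
        for rep in range(1, cfg.replicates + 1):
            rows.append((cond, "DMSO", np.nan, rep, cfg.dmso_level))
            rows.append((cond, "FCCP", np.nan, rep, cfg.fccp_level))
        for pep, conc in cfg.panel:
            f = peps.get((pep, conc))
            if f is None:
                continue
            truth_rows.append((cond, pep, conc, f))
            for rep in range(1, cfg.replicates + 1):
                signal = cfg.dmso_level - f * span
                rows.append((cond, pep, conc, rep, signal))
    df = pd.DataFrame(
        rows, columns=["condition", "peptide", "concentration_um", "replicate", "tmre_signal"]
    )
    if cfg.noise_sd > 0:
        df["tmre_signal"] += rng.normal(0.0, cfg.noise_sd, size=len(df))
    truth = pd.DataFrame(
        truth_rows, columns=["condition", "peptide", "concentration_um", "true_fraction"]
    )
    return Bh3Data(measurements=df, truth=SimulationTruth(bh3=truth))


# ---------------------------------------------------------------------------
# dose-response viability
# ---------------------------------------------------------------------------


def four_pl(dose: np.ndarray, top: float, bottom: float, ic50: float, hill: float) -> np.ndarray:
    """Four-parameter logistic response in dose (sigmoid in log10 dose)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def simulate_dose_response(
    ic50: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    doses: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Viability table following a 4PL curve; noise-free at ``noise_sd=0``."""
    if ic50 <= 0:
        raise ConfigError("ic50 must be positive")
    if doses is None:
        doses = np.logspace(-3, 1, 8)
    doses = np.asarray(list(doses), dtype=float)
    if np.any(doses <= 0):
        raise ConfigError("doses must be positive")
    rng = np.random.default_rng(seed)
    response = four_pl(doses, top, bottom, ic50, hill)
    if noise_sd > 0:
        response = response + rng.normal(0.0, noise_sd, size=response.shape)
    return pd.DataFrame({"dose": doses, "response": response})
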