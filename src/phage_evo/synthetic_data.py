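"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of a :class:`SimulationConfig` (seed
included): the same config reproduces bit-identical output. Defaults
encode the study conditions the analyses assume — logistic growth read
every 30 min for 24 h in triplicate, a 180-strain x 8-phage endpoint
RBG design with a bimodal score distribution (modes near 0.034 and
0.977), 7-day serial-passage selective sweeps sampled as binomial read
counts, 20-colony competition phenotyping, and a 3-replicate
transposon-library screen with planted enriched genes.

The generated data emulate the statistical structure of the real assays
(noise scales, sampling designs, sweep kinetics), not their mechanistic
biology: no adsorption kinetics, burst sizes or phage population
dynamics are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .growth_kinetics import GrowthCurve
from .fitness_metrics import CompetitionAssay
from .mutation_analysis import VariantRecord
from .resistance_scoring import InteractionMeasurement
from .tnseq_enrichment import InsertionCountTable

# distinct rng streams per generator, all derived from the one config seed
_STREAM_GROWTH = 1
_STREAM_RBG = 2
_STREAM_SWEEP = 3
_STREAM_COMPETITION = 4
_STREAM_TNSEQ = 5
_STREAM_STUDY_TABLE = 6


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth-curve parameters (per-hour rate, OD units)."""

    r: float = 0.8
    K: float = 1.0
    N0: float = 0.01
    noise_sd: float = 0.005
    t_max: float = 24.0
    dt: float = 0.5
    n_replicates: int = 3
    relative_rates: tuple[float, ...] = (1.0,)
    resistant: tuple[bool, ...] | None = None  # per strain; default all sensitive
    lysis_decline: bool = False  # sensitive-under-phage declines instead of flat


@dataclass(frozen=True)
class RBGMixtureParams:
    """Bimodal RBG mixture matching the observed mode locations."""

    mode_low: float = 0.034
    mode_high: float = 0.977
    concentration: float = 200.0
    weight_resistant: float = 0.39
    n_strains: int = 180
    n_phages: int = 8
    n_replicates: int = 3
    ctrl_start: float = 0.05
    ctrl_growth: float = 0.80


@dataclass(frozen=True)
class SweepParams:
    """Logistic selective sweeps per receptor class (per-day rates)."""

    s: float = 7.0
    f0: float = 0.01
    onset_lps: float = 0.0
    onset_btub: float = 3.0
    lps_gene: str = "rfaJ"
    btub_gene: str = "btuB"
    depth: int = 100
    timepoints: tuple[float, ...] = (0.5, 1.0, 3.0, 5.0, 7.0)
    n_replicates: int = 3


@dataclass(frozen=True)
class CompetitionParams:
    true_W: float = 0.93
    t0_density: float = 1e5
    wt_fold_growth: float = 1e4
    colonies_sampled: int = 20
    n_assays: int = 3


@dataclass(frozen=True)
class TnseqParams:
    n_genes: int = 500
    n_enriched: int = 10
    multiplier: float = 2.0**12
    library_size: int = 1_000_000
    n_replicates: int = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Master config; ``seed`` fixes every generator bit-for-bit."""

    seed: int = 0
    growth: GrowthParams = field(default_factory=GrowthParams)
    rbg: RBGMixtureParams = field(default_factory=RBGMixtureParams)
    sweep: SweepParams = field(default_factory=SweepParams)
    competition: CompetitionParams = field(default_factory=CompetitionParams)
    tnseq: TnseqParams = field(default_factory=TnseqParams)
    moi: float = 10.0

    def __post_init__(self) -> None:
        g = self.growth
        if min(g.r, g.K, g.N0, g.dt, g.t_max) <= 0 or g.noise_sd < 0:
            raise ValueError("growth parameters must be positive (noise_sd >= 0)")
        if not 0.0 <= self.rbg.weight_resistant <= 1.0:
            raise ValueError("weight_resistant must be in [0, 1]")
        if not 0.0 < self.competition.true_W < 2.0:
            raise ValueError("true_W must be in (0, 2)")
        if self.sweep.s <= 0 or not 0 < self.sweep.f0 < 1:
            raise ValueError("sweep needs s > 0 and f0 in (0, 1)")
        if self.tnseq.n_enriched > self.tnseq.n_genes:
            raise ValueError("enriched set larger than gene set")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def logistic_od(t: np.ndarray, r: float, K: float, N0: float) -> np.ndarray:
    """Closed-form logistic growth curve."""
    return K / (1.0 + (K / N0 - 1.0) * np.exp(-r * np.asarray(t, dtype=float)))


def gen_growth_curves(cfg: SimulationConfig) -> list[GrowthCurve]:
    """Control and phage-treated curve pairs for each simulated strain.

    Strain *i* grows logistically at rate ``r * relative_rates[i]`` with
    additive Gaussian noise (clipped at 0 OD). Under phage, resistant
    strains grow as the control; sensitive strains stay flat at the
    inoculum (or decline exponentially with ``lysis_decline``).
    """
    g = cfg.growth
    rng = cfg.rng(_STREAM_GROWTH)
    times = np.arange(0.0, g.t_max + g.dt / 2, g.dt)
    resistant = g.resistant or tuple(False for _ in g.relative_rates)
    if len(resistant) != len(g.relative_rates):
        raise ValueError("resistant flags must align with relative_rates")

    curves = []
    for i, (ratio, is_res) in enumerate(zip(g.relative_rates, resistant)):
        clean = logistic_od(times, g.r * ratio, g.K, g.N0)
        if is_res:
            treated_clean = clean
        elif g.lysis_decline:
            treated_clean = g.N0 * np.exp(-0.2 * times)
        else:
            treated_clean = np.full_like(times, g.N0)
        for rep in range(1, g.n_replicates + 1):
            for phage, base in ((None, clean), ("phage", treated_clean)):
                od = np.clip(base + rng.normal(0, g.noise_sd, len(times)), 0.0, None)
                curves.append(
                    GrowthCurve(
                        sample_id=f"strain_{i}" + ("" if phage is None else "+phage"),
                        strain_id=f"strain_{i}",
                        phage_treatment=phage,
                        replicate=rep,
                        times=times,
                        od=od,
                    )
                )
    return curves


def _beta_draw(rng, mean: float, concentration: float, size=None):
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return rng.beta(a, b, size=size)


def _measurements_for_cell(
    rng, strain, selecting, phage, resistant: bool, p: RBGMixtureParams
) -> list[InteractionMeasurement]:
    mean = p.mode_high if resistant else p.mode_low
    out = []
    for rep in range(1, p.n_replicates + 1):
        rbg = _beta_draw(rng, mean, p.concentration)
        out.append(
            InteractionMeasurement(
                strain_id=strain,
                selecting_phage=selecting,
                focal_phage=phage,
                replicate=rep,
                abs_start_phage=p.ctrl_start,
                abs_end_phage=p.ctrl_start + rbg * p.ctrl_growth,
                abs_start_ctrl=p.ctrl_start,
                abs_end_ctrl=p.ctrl_start + p.ctrl_growth,
            )
        )
    return out


def gen_interaction_rbg(
    cfg: SimulationConfig,
) -> tuple[list[InteractionMeasurement], dict[tuple[str, str], bool]]:
    """Endpoint-absorbance measurements with a bimodal mean-RBG structure.

    Each (strain, phage) cell is independently resistant with probability
    ``weight_resistant``; its replicate RBG values are Beta draws around
    the corresponding mixture mode, converted back to endpoint
    absorbances. Returns the measurements and the ground-truth
    resistant-cell labels.
    """
    p = cfg.rbg
    rng = cfg.rng(_STREAM_RBG)
    measurements = []
    labels: dict[tuple[str, str], bool] = {}
    phages = [f"phage_{j}" for j in range(p.n_phages)]
    for i in range(p.n_strains):
        strain = f"strain_{i:03d}"
        selecting = phages[i % p.n_phages]
        for phage in phages:
            resistant = bool(rng.random() < p.weight_resistant)
            labels[(strain, phage)] = resistant
            measurements.extend(
                _measurements_for_cell(rng, strain, selecting, phage, resistant, p)
            )
    return measurements, labels


#: Receptor layout of the eight-phage panel: four core-targeting phages,
#: one O-antigen-targeting phage, three BtuB-targeting phages.
STUDY_PHAGE_RECEPTORS = {
    "phage_core_1": "core",
    "phage_core_2": "core",
    "phage_core_3": "core",
    "phage_core_4": "core",
    "phage_O_1": "O-antigen",
    "phage_btub_1": "BtuB",
    "phage_btub_2": "BtuB",
    "phage_btub_3": "BtuB",
}

#: Planted design constants of the synthetic study table: strains selected
#: per receptor group, how many remain resistant to their focal phage, and
#: how many of those are cross-resistant to the other LPS group.
STUDY_DESIGN = {
    "selected": {"core": 80, "O-antigen": 40, "BtuB": 60},
    "focal_resistant": {"core": 76, "O-antigen": 37, "BtuB": 53},
    "cross": {("core", "O-antigen"): 34, ("O-antigen", "core"): 8},
}

#: Strains whole-genome sequenced per selecting-receptor group in the
#: synthetic study design (a subset of the focal-resistant strains).
STUDY_WGS_GROUPS = {"core": 35, "O-antigen": 20, "BtuB": 4}


def gen_study_rbg_table(
    seed: int = 0, rbg_params: RBGMixtureParams | None = None
) -> tuple[list[InteractionMeasurement], dict[str, str]]:
    """Synthetic stand-in for the full 180 x 8 resistance screen.

    Plants the screen's marginal structure exactly: 80/40/60 strains
    selected by core-, O-antigen- and BtuB-targeting phages, of which
    76/37/53 stay resistant to their focal phage (166 of 180 overall);
    34 of the 76 core-selected resistants are cross-resistant to the
    O-antigen phage and 8 of the 37 O-selected resistants to all four
    core phages; same-receptor cross-resistance is complete and BtuB
    cross-resistance absent. Replicate RBG values are Beta draws around
    the mixture modes. Returns the measurements and the phage -> receptor
    map.
    """
    p = rbg_params or RBGMixtureParams()
    rng = np.random.default_rng([seed, _STREAM_STUDY_TABLE])
    phages = list(STUDY_PHAGE_RECEPTORS)
    by_group: dict[str, list[str]] = {}
    for phage, group in STUDY_PHAGE_RECEPTORS.items():
        by_group.setdefault(group, []).append(phage)

    measurements: list[InteractionMeasurement] = []
    for group, n_selected in STUDY_DESIGN["selected"].items():
        group_phages = by_group[group]
        n_resistant = STUDY_DESIGN["focal_resistant"][group]
        cross_to: dict[str, int] = {
            tgt: n for (src, tgt), n in STUDY_DESIGN["cross"].items() if src == group
        }
        for k in range(n_selected):
            selecting = group_phages[k % len(group_phages)]
            strain = f"{group}_sel_{k:02d}"
            focal_resistant = k < n_resistant
            for phage in phages:
                target_group = STUDY_PHAGE_RECEPTORS[phage]
                if not focal_resistant:
                    resistant = False
                elif target_group == group:
                    resistant = True
                else:
                    resistant = k < cross_to.get(target_group, 0)
                measurements.extend(
                    _measurements_for_cell(rng, strain, selecting, phage, resistant, p)
                )
    return measurements, dict(STUDY_PHAGE_RECEPTORS)


def sweep_frequency(t, s: float, f0: float, onset: float):
    """Logistic allele-frequency sweep, 0 before onset."""
    t = np.asarray(t, dtype=float)
    e = np.exp(s * (t - onset))
    f = f0 * e / (1.0 + f0 * (e - 1.0))
    return np.where(t >= onset, f, 0.0)


def gen_variant_timeseries(cfg: SimulationConfig) -> list[VariantRecord]:
    """Population variant calls of staggered receptor-gene sweeps.

    An LPS-gene allele (default a *rfaJ* missense) sweeps from
    ``onset_lps`` and a *btuB* frameshift from ``onset_btub``; observed
    frequencies are binomial draws at the configured read depth.
    Timepoints where no read carries the allele emit no record.
    """
    sw = cfg.sweep
    if sw.onset_lps > sw.onset_btub:
        raise ValueError("onsets must be ordered: LPS sweep cannot start after BtuB")
    rng = cfg.rng(_STREAM_SWEEP)
    alleles = (
        (sw.lps_gene, "missense", "H263N", "805:C>A", None, sw.onset_lps),
        (sw.btub_gene, "frameshift", None, "1 bp del.", 1, sw.onset_btub),
    )
    records = []
    for rep in range(1, sw.n_replicates + 1):
        for gene, mtype, aa, nt, indel, onset in alleles:
            for t in sw.timepoints:
                f = float(sweep_frequency(t, sw.s, sw.f0, onset))
                observed = rng.binomial(sw.depth, f) / sw.depth
                if observed == 0.0:
                    continue
                records.append(
                    VariantRecord(
                        sample_id=f"rep{rep}",
                        gene=gene,
                        mutation_type=mtype,
                        nt_change=nt,
                        aa_change=aa,
                        frequency=observed,
                        timepoint=t,
                        indel_len=indel,
                    )
                )
    return records


def gen_competition_assay(cfg: SimulationConfig) -> list[CompetitionAssay]:
    """Competition assays with known true fitness.

    The wild type grows ``wt_fold_growth``-fold in 24 h; the resistant
    strain grows ``wt_fold_growth ** true_W``-fold, so the generating
    relative fitness is exactly ``true_W``. Colony phenotyping is a
    binomial sample of ``colonies_sampled`` colonies.
    """
    c = cfg.competition
    rng = cfg.rng(_STREAM_COMPETITION)
    g_s = c.wt_fold_growth
    g_r = g_s**c.true_W
    t24_res = c.t0_density * g_r
    t24_wt = c.t0_density * g_s
    total = t24_res + t24_wt
    p_wt = t24_wt / total
    return [
        CompetitionAssay(
            t0_resistant=c.t0_density,
            t0_wt=c.t0_density,
            t24_total=total,
            colonies_sampled=c.colonies_sampled,
            colonies_wt=int(rng.binomial(c.colonies_sampled, p_wt)),
        )
        for _ in range(c.n_assays)
    ]


def gen_tnseq_counts(cfg: SimulationConfig) -> tuple[InsertionCountTable, list[str]]:
    """Insertion-count table with planted enriched genes.

    Control replicates are multinomial draws over fixed per-gene library
    weights; infected replicates reweight the first ``n_enriched`` genes
    by ``multiplier``. Returns the table and the planted gene names.
    """
    t = cfg.tnseq
    rng = cfg.rng(_STREAM_TNSEQ)
    genes = [f"gene_{i:04d}" for i in range(t.n_genes)]
    enriched = genes[: t.n_enriched]
    base = rng.gamma(2.0, size=t.n_genes)
    base /= base.sum()
    infected_w = base.copy()
    infected_w[: t.n_enriched] *= t.multiplier
    infected_w /= infected_w.sum()

    columns = {}
    for rep in range(1, t.n_replicates + 1):
        columns[("control", rep)] = rng.multinomial(t.library_size, base)
    for rep in range(1, t.n_replicates + 1):
        columns[("infected", rep)] = rng.multinomial(t.library_size, infected_w)
    counts = pd.DataFrame(columns, index=genes)
    counts.columns = pd.MultiIndex.from_tuples(
        counts.columns, names=["condition", "replicate"]
    )
    return InsertionCountTable(counts=counts), enriched


# ---------------------------------------------------------------------------
# Fixture writing (simulate-all)

def write_fixtures(cfg: SimulationConfig, outdir) -> dict[str, str]:
    """Write every input format the analysis modules read; returns paths."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    curves = gen_growth_curves(cfg)
    growth_rows = [
        {"sample": c.sample_id, "strain": c.strain_id, "phage": c.phage_treatment,
         "replicate": c.replicate, "time_h": t, "od600": od}
        for c in curves for t, od in zip(c.times, c.od)
    ]
    paths["growth"] = str(outdir / "growth.csv")
    pd.DataFrame(growth_rows).to_csv(paths["growth"], index=False)

    measurements, receptor_map = gen_study_rbg_table(cfg.seed, cfg.rbg)
    rbg_rows = [
        {"strain": m.strain_id, "selecting_phage": m.selecting_phage,
         "focal_phage": m.focal_phage, "replicate": m.replicate,
         "a0_phage": m.abs_start_phage, "a8_phage": m.abs_end_phage,
         "a0_ctrl": m.abs_start_ctrl, "a8_ctrl": m.abs_end_ctrl,
         "endpoint_h": m.endpoint_h}
        for m in measurements
    ]
    paths["interactions"] = str(outdir / "interactions.csv")
    pd.DataFrame(rbg_rows).to_csv(paths["interactions"], index=False)
    paths["receptor_map"] = str(outdir / "receptors.yaml")
    Path(paths["receptor_map"]).write_text(yaml.safe_dump(receptor_map))

    variants = gen_variant_timeseries(cfg)
    var_rows = [
        {"sample": v.sample_id, "timepoint": v.timepoint, "gene": v.gene,
         "mutation_type": v.mutation_type, "nt_change": v.nt_change,
         "aa_change": v.aa_change, "frequency": v.frequency,
         "indel_len": v.indel_len}
        for v in variants
    ]
    paths["variants"] = str(outdir / "variants.tsv")
    pd.DataFrame(var_rows).to_csv(paths["variants"], sep="\t", index=False)

    assays = gen_competition_assay(cfg)
    comp_rows = [
        {"t0_r": a.t0_resistant, "t0_s": a.t0_wt, "t24_total": a.t24_total,
         "n_sampled": a.colonies_sampled, "n_wt": a.colonies_wt}
        for a in assays
    ]
    paths["competition"] = str(outdir / "competition.csv")
    pd.DataFrame(comp_rows).to_csv(paths["competition"], index=False)

    table, _ = gen_tnseq_counts(cfg)
    long = table.counts.stack(["condition", "replicate"], future_stack=True)
    long = long.rename("count").reset_index().rename(columns={"level_0": "gene"})
    if "gene" not in long.columns:
        long = long.rename(columns={long.columns[0]: "gene"})
    paths["tnseq"] = str(outdir / "tnseq_counts.tsv")
    long.to_csv(paths["tnseq"], sep="\t", index=False)

    return paths
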