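"""Synthetic data generation for every stage of the pipeline.

Emulates a saturation-mutagenesis selection on DHFR across TYMS
backgrounds: per-mutant ground-truth kinetics drawn from a bimodal
catalytic-power prior, growth rates computed through the velocity-to-growth
model, exponential lineage dynamics over the selection timepoints sampled
multinomially at fixed sequencing depth in triplicate (with a WT reference
lineage), plus noisy in-vitro kinetics and metabolomics-style THF tables.
Everything is deterministic under a fixed seed, so all downstream stages
are testable without any external download.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalytic import DHFR_WT
from .core_model import (
    NEAR_INACTIVE,
    EnzymeKinetics,
    GrowthLaw,
    ModelParams,
    _predict_growth_arrays,
)
from .counts import AA_TO_CODONS, CountTable, ReferenceMap
from .fitting import ObservationSet

__all__ = [
    "DEFAULT_BACKGROUNDS",
    "TYMS_VARIANTS",
    "TYMS_CONCS",
    "default_model_params",
    "dhfr_reference_panel",
    "KineticsPrior",
    "TruthTable",
    "SelectionSpec",
    "generate_truth_table",
    "simulate_selection_counts",
    "generate_observation_set",
    "generate_invitro_tables",
    "generate_metabolomics_table",
    "export_dataset",
    "random_reference",
    "emit_sample_fastq",
]

#: backgrounds carried by the selection experiment
DEFAULT_BACKGROUNDS = ("WT", "Q33S", "R166Q")

#: TYMS variant kinetics: WT; a partial loss-of-function expressed at
#: elevated concentration so its Vmax exceeds WT (negative-epistasis
#: regime); an intermediate loss-of-function; and a near-inactive variant
#: carried at sentinel kinetics
TYMS_VARIANTS: dict[str, EnzymeKinetics] = {
    "WT": EnzymeKinetics(kcat=5.0, km=20.0),
    "Q33S": EnzymeKinetics(kcat=2.5, km=20.0),
    "R127A": EnzymeKinetics(kcat=0.5, km=20.0),
    "R166Q": NEAR_INACTIVE,
}

TYMS_CONCS: dict[str, float] = {"WT": 1.0, "Q33S": 3.0, "R127A": 1.0, "R166Q": 0.5}

DEFAULT_GROWTH_LAW = GrowthLaw(g_max=1.0, g_min=0.1, K=0.037, n=1.0)


def default_model_params(
    backgrounds: Sequence[str] = ("WT", "Q33S", "R127A", "R166Q"),
) -> ModelParams:
    """The generating parameter set used as the study condition.

    The Michaelis constants sit at or above the folate pool size, so the
    cycle operates between the zero- and first-order regimes: growth then
    depends on each enzyme's catalytic power (kcat/Km), reproducing the
    degeneracy structure the catalytic inference exploits, while the
    landscape still varies visibly along both kcat and Km.
    """
    return ModelParams(
        growth_law=DEFAULT_GROWTH_LAW,
        dhfr_conc=1.0,
        tyms_concs={bg: TYMS_CONCS[bg] for bg in backgrounds},
        fol_tot=5.0,
        thf_scale=1.0,
        tyms_kinetics={bg: TYMS_VARIANTS[bg] for bg in backgrounds},
    )


def dhfr_reference_panel() -> dict[str, EnzymeKinetics]:
    """Seven characterized DHFR variants spanning the activity range.

    Offsets in log10 catalytic power from WT cover the full
    velocity-to-growth transition, mirroring a panel of single and double
    mutants selected for that purpose.
    """
    offsets = [0.0, -0.7, -1.2, -1.6, -2.0, -2.6, -3.5]
    km_factors = [1.0, 2.0, 0.5, 3.0, 1.5, 1.0, 2.0]
    panel = {}
    for i, (off, kf) in enumerate(zip(offsets, km_factors)):
        km = DHFR_WT.km * kf
        kcat = 10.0 ** (DHFR_WT.log10_power + off) * km
        name = "WT" if off == 0.0 else f"D{i}"
        panel[name] = EnzymeKinetics(kcat=kcat, km=km)
    return panel


@dataclass(frozen=True)
class KineticsPrior:
    """Bimodal prior over log10 catalytic power offsets from WT.

    A near-neutral mode and a deleterious mode, mixed at position level
    with weight ``w_deleterious`` (0.12 by default, reproducing a
    bimodal growth-rate distribution with roughly that fraction of
    mutations at or below the inactive level).  Position means scatter
    around the mode centers and individual substitutions scatter within
    a position, giving positionally coherent mutational effects.
    """

    w_deleterious: float = 0.12
    deleterious_mean: float = -5.0
    deleterious_pos_sd: float = 0.6
    deleterious_within_sd: float = 0.8
    neutral_mean: float = -0.2
    neutral_pos_sd: float = 0.3
    neutral_within_sd: float = 0.6
    km_sd_decades: float = 0.3


@dataclass
class TruthTable:
    """Ground truth per mutant: kinetics and model growth per background.

    Growth columns ``growth_<bg>`` are WT-relative (the model prediction
    divided by the WT variant's prediction in the same background), so the
    WT row is exactly 1 in every background.
    """

    data: pd.DataFrame
    params: ModelParams
    backgrounds: tuple[str, ...]

    @property
    def mutants(self) -> list[str]:
        return [m for m in self.data["mutant"] if m != "WT"]

    def growth(self, background: str) -> pd.Series:
        return self.data.set_index("mutant")[f"growth_{background}"]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class SelectionSpec:
    """Turbidostat selection design: schedule, depth, noise, seed.

    Timepoints in hours (samples at 4, 8, 12, 20 and 24 h after the t=0
    reference), triplicate vials, fixed reads per sample, bulk culture
    growth in doublings/hour, a per-replicate growth-rate jitter
    (vial-to-vial biology), per-base sequencing error (FASTQ emission
    only) and a WT lineage carried at a multiple of a single mutant's
    initial abundance.
    """

    timepoints: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 20.0, 24.0)
    replicates: int = 3
    depth: int = 500_000
    bulk_rate: float = 0.35
    rep_growth_sd: float = 0.005
    error_rate: float = 0.001
    wt_weight: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        tp = self.timepoints
        if list(tp) != sorted(tp) or tp[0] != 0:
            raise ValueError("timepoints must be sorted and start at 0")


_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def generate_truth_table(
    n_positions: int = 16,
    alphabet: str = _AA20,
    prior: KineticsPrior = KineticsPrior(),
    params: ModelParams | None = None,
    backgrounds: Sequence[str] = DEFAULT_BACKGROUNDS,
    mutants_per_position: int | None = None,
    reference: ReferenceMap | None = None,
    seed: int = 0,
) -> TruthTable:
    """Draw ground-truth kinetics and growth for a single-mutant library.

    Each position carries ``mutants_per_position`` substitutions (default:
    every non-WT amino acid of the alphabet).  Mode membership is drawn at
    position level so substitutions at one position have coherent effects;
    growth rates are computed through the model for every background and
    normalized to the WT variant.
    """
    if params is None:
        params = default_model_params()
    rng = np.random.default_rng(seed)
    wt_power = DHFR_WT.log10_power
    if reference is not None:
        wt_aa = reference.wt_protein[:n_positions]
    else:
        wt_aa = "".join(rng.choice(list(alphabet), size=n_positions))
    rows = [
        {
            "mutant": "WT",
            "position": pd.NA,
            "aa": pd.NA,
            "kcat": DHFR_WT.kcat,
            "km": DHFR_WT.km,
        }
    ]
    for pos in range(1, n_positions + 1):
        deleterious = rng.random() < prior.w_deleterious
        if deleterious:
            pos_mean = rng.normal(prior.deleterious_mean, prior.deleterious_pos_sd)
            within_sd = prior.deleterious_within_sd
        else:
            pos_mean = rng.normal(prior.neutral_mean, prior.neutral_pos_sd)
            within_sd = prior.neutral_within_sd
        choices = [a for a in alphabet if a != wt_aa[pos - 1]]
        if mutants_per_position is not None:
            choices = list(
                rng.choice(choices, size=mutants_per_position, replace=False)
            )
        for aa in choices:
            offset = rng.normal(pos_mean, within_sd)
            km = DHFR_WT.km * 10.0 ** rng.normal(0.0, prior.km_sd_decades)
            kcat = 10.0 ** (wt_power + offset) * km
            rows.append(
                {
                    "mutant": f"{wt_aa[pos - 1]}{pos}{aa}",
                    "position": pos,
                    "aa": aa,
                    "kcat": kcat,
                    "km": km,
                }
            )
    data = pd.DataFrame(rows)
    data["log10_power"] = np.log10(data["kcat"] / data["km"])
    kcat = data["kcat"].to_numpy(float)
    km = data["km"].to_numpy(float)
    for bg in backgrounds:
        g = _predict_growth_arrays(kcat, km, bg, params)
        g_wt = _predict_growth_arrays(
            np.array([DHFR_WT.kcat]), np.array([DHFR_WT.km]), bg, params
        )[0]
        data[f"growth_{bg}"] = g / g_wt
    return TruthTable(data=data, params=params, backgrounds=tuple(backgrounds))


def _background_rng(spec: SelectionSpec, background: str) -> np.random.Generator:
    return np.random.default_rng(
        [spec.seed, zlib.crc32(background.encode("ascii"))]
    )


def simulate_selection_counts(
    truth: TruthTable,
    spec: SelectionSpec,
    background: str = "WT",
    exact: bool = False,
) -> CountTable:
    """Simulate sequencing counts of the selection in one TYMS background.

    Lineages grow exponentially, A_m(t) = A_m(0) * 2^(rate_m * bulk * t),
    with the WT lineage at rate exactly 1 and an initial abundance
    ``wt_weight`` times a mutant's.  Each replicate vial perturbs mutant
    rates by a small Gaussian jitter; per-sample counts are multinomial at
    the specified depth (or, with ``exact=True``, the expected counts
    without sampling noise).
    """
    rng = _background_rng(spec, background)
    rates = truth.growth(background)
    mutants = list(rates.index)
    base_rates = rates.to_numpy(float)
    a0 = np.where(np.array(mutants) == "WT", spec.wt_weight, 1.0)
    meta = truth.data.set_index("mutant")[["position", "aa"]]
    times = np.asarray(spec.timepoints)
    rows = []
    for rep in range(1, spec.replicates + 1):
        jitter = rng.normal(0.0, spec.rep_growth_sd, size=len(mutants))
        jitter[np.array(mutants) == "WT"] = 0.0
        rep_rates = np.clip(base_rates + jitter, 0.0, None)
        log_a = np.log2(a0)[:, None] + rep_rates[:, None] * spec.bulk_rate * times
        log_a -= log_a.max(axis=0, keepdims=True)  # overflow guard
        abundance = 2.0**log_a
        freqs = abundance / abundance.sum(axis=0, keepdims=True)
        for ti, t in enumerate(times):
            if exact:
                counts = spec.depth * freqs[:, ti]
            else:
                counts = rng.multinomial(spec.depth, freqs[:, ti])
            for m, c in zip(mutants, counts):
                rows.append(
                    {
                        "mutant": m,
                        "position": meta.loc[m, "position"],
                        "aa": meta.loc[m, "aa"],
                        "timepoint_h": t,
                        "replicate": rep,
                        "count": c,
                    }
                )
    return CountTable(pd.DataFrame(rows))


def generate_observation_set(
    params: ModelParams | None = None,
    dhfr_panel: Mapping[str, EnzymeKinetics] | None = None,
    backgrounds: Sequence[str] = ("WT", "Q33S", "R127A", "R166Q"),
    growth_noise: float = 0.02,
    n_replicates: int = 3,
    with_thf: bool = False,
    thf_noise: float = 0.1,
    seed: int = 0,
) -> ObservationSet:
    """Plate-reader-style observations: DHFR panel x TYMS backgrounds.

    Growth is the model prediction under multiplicative lognormal noise
    (default 2% CV) averaged over replicates, with the replicate SEM
    recorded; optionally a THF-abundance readout with its own noise is
    included (metabolomics-style observations).
    """
    if params is None:
        params = default_model_params(backgrounds)
    if dhfr_panel is None:
        dhfr_panel = dhfr_reference_panel()
    rng = np.random.default_rng(seed)
    rows = []
    for dname, dkin in dhfr_panel.items():
        for bg in backgrounds:
            tyms = params.tyms_kinetics[bg]
            g_true = float(
                _predict_growth_arrays(
                    np.array([dkin.kcat]), np.array([dkin.km]), bg, params
                )[0]
            )
            reps = g_true * rng.lognormal(0.0, growth_noise, size=n_replicates)
            row = {
                "dhfr_variant": dname,
                "tyms_variant": bg,
                "dhfr_kcat": dkin.kcat,
                "dhfr_km": dkin.km,
                "tyms_kcat": tyms.kcat,
                "tyms_km": tyms.km,
                "growth": float(np.mean(reps)),
                "growth_sem": float(np.std(reps, ddof=1) / np.sqrt(n_replicates)),
                "n_replicates": n_replicates,
                "growth_true": g_true,
            }
            if with_thf:
                from .fitting import _predict_thf_abundance

                thf_true = float(
                    _predict_thf_abundance(pd.DataFrame([row]), params)[0]
                )
                thf_reps = thf_true * rng.lognormal(0.0, thf_noise, size=n_replicates)
                row["thf_abundance"] = float(np.mean(thf_reps))
                row["thf_sd"] = float(np.std(thf_reps, ddof=1))
                row["thf_true"] = thf_true
            rows.append(row)
    return ObservationSet(pd.DataFrame(rows))


def generate_invitro_tables(
    truth: TruthTable,
    mutants: Sequence[str] | None = None,
    noise: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """In-vitro Michaelis-Menten tables with replicate scatter.

    Lognormal multiplicative noise on kcat and Km, ``n_replicates`` rows
    per variant; noise 0 reproduces the truth exactly.
    """
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    sub = truth.data if mutants is None else truth.data[
        truth.data["mutant"].isin(mutants)
    ]
    rows = []
    for row in sub.itertuples(index=False):
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "variant": row.mutant,
                    "enzyme": "DHFR",
                    "replicate": rep,
                    "kcat_per_s": row.kcat * rng.lognormal(0.0, noise),
                    "km_uM": row.km * rng.lognormal(0.0, noise),
                }
            )
    return pd.DataFrame(rows)


def generate_metabolomics_table(
    truth: TruthTable,
    mutants: Sequence[str] | None = None,
    backgrounds: Sequence[str] = ("WT", "R166Q"),
    noise: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Metabolomics-style THF abundance table through the model.

    Abundance = thf_scale * fol_tot * steady-state fraction with
    lognormal noise, in triplicate, for each mutant x background pair.
    """
    if noise < 0:
        raise ValueError("noise must be >= 0")
    from .fitting import _predict_thf_abundance

    params = truth.params
    rng = np.random.default_rng(seed)
    sub = truth.data if mutants is None else truth.data[
        truth.data["mutant"].isin(mutants)
    ]
    rows = []
    for row in sub.itertuples(index=False):
        for bg in backgrounds:
            tyms = params.tyms_kinetics[bg]
            frame = pd.DataFrame(
                [
                    {
                        "dhfr_kcat": row.kcat,
                        "dhfr_km": row.km,
                        "tyms_kcat": tyms.kcat,
                        "tyms_km": tyms.km,
                        "tyms_variant": bg,
                    }
                ]
            )
            thf_true = float(_predict_thf_abundance(frame, params)[0])
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "dhfr_variant": row.mutant,
                        "tyms_variant": bg,
                        "dhfr_kcat": row.kcat,
                        "dhfr_km": row.km,
                        "tyms_kcat": tyms.kcat,
                        "tyms_km": tyms.km,
                        "replicate": rep,
                        "thf_abundance": thf_true * rng.lognormal(0.0, noise),
                        "thf_true": thf_true,
                    }
                )
    return pd.DataFrame(rows)


def export_dataset(
    truth: TruthTable,
    spec: SelectionSpec,
    directory,
    backgrounds: Sequence[str] | None = None,
) -> dict:
    """Write a complete synthetic dataset plus a regeneration manifest.

    Emits the truth table, one selection count table per background, and
    a ``manifest.yaml`` recording the seeds, selection design and model
    parameters needed to regenerate the files exactly.  Returns the
    manifest dict.
    """
    import dataclasses
    import os

    import yaml

    from .io import params_to_yaml

    backgrounds = list(truth.backgrounds if backgrounds is None else backgrounds)
    os.makedirs(directory, exist_ok=True)
    truth.to_csv(os.path.join(directory, "truth.csv"))
    for bg in backgrounds:
        simulate_selection_counts(truth, spec, background=bg).to_csv(
            os.path.join(directory, f"counts_{bg}.csv")
        )
    params_to_yaml(truth.params, os.path.join(directory, "model_params.yaml"))
    manifest = {
        "selection_spec": dataclasses.asdict(spec),
        "backgrounds": backgrounds,
        "files": ["truth.csv", "model_params.yaml"]
        + [f"counts_{bg}.csv" for bg in backgrounds],
    }
    manifest["selection_spec"]["timepoints"] = list(spec.timepoints)
    with open(os.path.join(directory, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# sequence-level emission


def random_reference(
    n_codons: int = 159,
    windows: tuple[tuple[int, int], ...] | None = None,
    seed: int = 0,
) -> ReferenceMap:
    """Random stop-free coding sequence wrapped as a ReferenceMap."""
    rng = np.random.default_rng(seed)
    sense = [c for aa, cs in AA_TO_CODONS.items() if aa != "*" for c in cs]
    seq = "".join(rng.choice(sense, size=n_codons))
    if windows is None:
        if n_codons == 159:
            return ReferenceMap(seq)
        windows = ((1, n_codons),)
    return ReferenceMap(seq, windows)


def emit_sample_fastq(
    path,
    calls: Sequence,
    ref: ReferenceMap,
    window: int = 0,
    error_rate: float = 0.0,
    qual: int = 40,
    seed: int = 0,
) -> None:
    """Write one sample's reads as phred-33 FASTQ.

    Each call ("WT" or (position, aa)) becomes one fixed-length amplicon
    read over the window span, with a randomly chosen codon realizing the
    amino-acid change and optional uniform per-base substitution errors.
    """
    rng = np.random.default_rng(seed)
    start_nt, end_nt = ref.window_nt_span(window)
    wt_region = ref.wt_seq[start_nt:end_nt]
    w_start, _ = ref.windows[window]
    qline = chr(qual + 33) * len(wt_region)
    with open(path, "w") as fh:
        for i, call in enumerate(calls):
            seq = list(wt_region)
            if call != "WT":
                pos, aa = call
                codons = [
                    c
                    for c in AA_TO_CODONS[aa]
                    if c != ref.codon(pos)
                ]
                codon = codons[rng.integers(len(codons))]
                off = 3 * (pos - w_start)
                seq[off : off + 3] = codon
            if error_rate > 0:
                for j in range(len(seq)):
                    if rng.random() < error_rate:
                        seq[j] = rng.choice([b for b in "ACGT" if b != seq[j]])
            fh.write(f"@read{i}\n{''.join(seq)}\n+\n{qline}\n")
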