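"""Synthetic drug × time expression experiments with planted ground truth.

The generator emulates a psychotropic-drug microarray time-course study:
a panel of drugs (plus vehicle controls and a naive group) profiled at
1, 2, 4 and 8 h after administration, three replicate arrays per
drug × time cell (12 arrays per drug), with a two-batch structure
mimicking two array versions.

The signal model is bilinear: the expected log2 expression of probe p
in the group (drug d, time t) is

    baseline_p + sum_m A[m, p] * B[d, m] * shape_d(t)

where A holds per-mechanism transcript sensitivities, B the drug's
engagement of each pharmacological mechanism, and shape_d a
log-normal-like impulse in time peaking at the drug's characteristic
response time.  Co-expression modules are planted by giving all member
probes sensitivity to the same mechanism; module membership, A, B and
the full noise-free mean surface are returned as ground truth for
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

TIME_POINTS_DEFAULT = (1.0, 2.0, 4.0, 8.0)
NAIVE_LABEL = "naive"


@dataclass
class DrugSpec:
    """One treatment arm: name, mechanism engagement, matched control."""

    name: str
    mechanisms: dict[str, float] = field(default_factory=dict)
    control: str | None = None
    peak_time_h: float = 2.0
    amplitude: float = 1.0
    is_vehicle: bool = False


@dataclass
class SyntheticConfig:
    """Full description of a synthetic experiment.

    ``noise_sd`` is the i.i.d. Gaussian replicate noise in log2-intensity
    units.  ``batch_effects`` maps batch label -> (additive shift,
    multiplicative scale) applied to the whole sample; defaults are the
    identity so the noise-free data equal the mean surface exactly.
    ``frac_up`` is the probability that a planted module is up- rather
    than down-regulated (direction is a module-level property so that
    members of one module are coherently co-expressed).
    """

    n_probes: int
    mechanisms: list[str]
    drugs: list[DrugSpec]
    network_sizes: tuple[int, ...] = (100, 40, 30)
    network_mechanisms: tuple[str, ...] | None = None
    time_points: tuple[float, ...] = TIME_POINTS_DEFAULT
    replicates_per_timepoint: int = 3
    noise_sd: float = 0.3
    batch_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"v1": (0.0, 1.0), "v2": (0.0, 1.0)}
    )
    frac_up: float = 0.9
    baseline_range: tuple[float, float] = (6.0, 12.0)
    shape_width: float = 1.0
    include_naive: bool = True
    naive_collapsed: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        if self.replicates_per_timepoint <= 0:
            raise ValueError("replicates_per_timepoint must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(s <= 0 for s in self.network_sizes):
            raise ValueError("network sizes must be positive")
        if sum(self.network_sizes) > self.n_probes:
            raise ValueError("planted networks exceed n_probes")
        tp = np.asarray(self.time_points, dtype=float)
        if len(tp) == 0 or np.any(np.diff(tp) <= 0) or np.any(tp <= 0):
            raise ValueError("time_points must be positive and strictly increasing")
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate drug names")
        for d in self.drugs:
            unknown = set(d.mechanisms) - set(self.mechanisms)
            if unknown:
                raise ValueError(
                    f"drug {d.name!r} references undeclared mechanisms {sorted(unknown)}"
                )
            if d.is_vehicle and d.mechanisms:
                raise ValueError(f"vehicle {d.name!r} must have no mechanisms")
            if not d.is_vehicle and not d.mechanisms:
                raise ValueError(f"non-vehicle drug {d.name!r} needs >= 1 mechanism")
        if self.network_mechanisms is not None:
            flat: set[str] = set()
            for g in self.network_mechanisms:
                flat.update([g] if isinstance(g, str) else g)
            unknown = flat - set(self.mechanisms)
            if unknown:
                raise ValueError(f"undeclared network mechanisms {sorted(unknown)}")

    @property
    def treatment_drugs(self) -> list[DrugSpec]:
        return [d for d in self.drugs if not d.is_vehicle]

    @property
    def vehicles(self) -> list[DrugSpec]:
        return [d for d in self.drugs if d.is_vehicle]

    def vehicle_map(self) -> dict[str, str]:
        """Map each treatment drug to its matched vehicle control."""
        vehicles = [v.name for v in self.vehicles]
        out = {}
        for d in self.treatment_drugs:
            if d.control is not None:
                out[d.name] = d.control
            elif len(vehicles) == 1:
                out[d.name] = vehicles[0]
            else:
                raise ValueError(
                    f"drug {d.name!r} has no matched control and several vehicles exist"
                )
        return out


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated experiment."""

    network_membership: pd.Series  # probe -> module label or "background"
    A_true: pd.DataFrame  # mechanism × probe sensitivities
    B_true: pd.DataFrame  # drug × mechanism engagement
    mean_surface: pd.DataFrame  # probe × (drug, time) expected log2 values
    vehicle_map: dict[str, str]


def impulse_shape(t, peak_time_h: float, width: float) -> np.ndarray:
    """Log-normal-like impulse, unit height at its peak time."""
    t = np.asarray(t, dtype=float)
    return np.exp(-((np.log(t) - np.log(peak_time_h)) ** 2) / (2.0 * width**2))


def generate_binding_matrix(config: SyntheticConfig) -> pd.DataFrame:
    """Drug × mechanism engagement matrix B (vehicle rows all zero)."""
    config.validate()
    B = pd.DataFrame(
        0.0, index=[d.name for d in config.drugs], columns=list(config.mechanisms)
    )
    for d in config.drugs:
        for mech, val in d.mechanisms.items():
            B.loc[d.name, mech] = float(val)
    return B


def generate_experiment(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one experiment: log2 expression matrix, sample sheet and truth.

    Identical config and seed give bit-identical output.  With
    ``noise_sd = 0`` and identity batch effects every sample equals its
    column of the mean surface exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_digits = max(4, len(str(config.n_probes)))
    probes = pd.Index(
        [f"p{i:0{n_digits}d}" for i in range(config.n_probes)], name="probe_id"
    )

    # --- planted module membership and sensitivities -------------------
    membership = pd.Series("background", index=probes, name="network")
    mech_cycle = (
        list(config.network_mechanisms)
        if config.network_mechanisms is not None
        else [config.mechanisms[i % len(config.mechanisms)] for i in range(len(config.network_sizes))]
    )
    A = pd.DataFrame(0.0, index=list(config.mechanisms), columns=probes)
    start = 0
    for k, size in enumerate(config.network_sizes):
        label = f"net_{k + 1}"
        members = probes[start : start + size]
        membership.loc[members] = label
        gains = rng.uniform(0.8, 1.2, size=size)
        # a network may be driven by one mechanism or a mechanism group
        group = mech_cycle[k]
        for mech in [group] if isinstance(group, str) else group:
            A.loc[mech, members] = gains
        start += size

    # Down-regulated affected transcripts are planted as scattered
    # singletons outside the modules (one mechanism each, negative
    # sensitivity) so that the up:down split of all affected transcripts
    # is frac_up while each module stays coherently co-expressed.
    n_module = sum(config.network_sizes)
    n_down = 0
    if n_module and config.frac_up < 1.0:
        n_down = int(round(n_module * (1.0 - config.frac_up) / config.frac_up))
        n_down = min(n_down, config.n_probes - n_module)
        down = probes[n_module : n_module + n_down]
        for i, p in enumerate(down):
            mech = config.mechanisms[i % len(config.mechanisms)]
            A.loc[mech, p] = -rng.uniform(0.8, 1.2)

    B = generate_binding_matrix(config)
    baseline = rng.uniform(*config.baseline_range, size=config.n_probes)

    # --- mean surface per (drug, time) group ---------------------------
    tp = tuple(float(t) for t in config.time_points)
    groups: list[tuple[str, float]] = []
    for d in config.drugs:
        groups.extend((d.name, t) for t in tp)
    if config.include_naive:
        naive_times = (tp[0],) if config.naive_collapsed else tp
        groups.extend((NAIVE_LABEL, t) for t in naive_times)

    spec_by_name = {d.name: d for d in config.drugs}
    cols = pd.MultiIndex.from_tuples(groups, names=["drug", "time_h"])
    mean_surface = pd.DataFrame(0.0, index=probes, columns=cols)
    for drug, t in groups:
        mu = baseline.copy()
        if drug != NAIVE_LABEL:
            d = spec_by_name[drug]
            if not d.is_vehicle:
                shape = impulse_shape(t, d.peak_time_h, config.shape_width)
                effect = A.to_numpy().T @ B.loc[drug].to_numpy()
                mu = mu + d.amplitude * shape * effect
        mean_surface[(drug, t)] = mu

    # --- samples: replicate noise, batch structure ---------------------
    batch_labels = sorted(config.batch_effects)
    sample_ids, rows, data = [], [], []
    for drug, t in groups:
        is_vehicle = drug != NAIVE_LABEL and spec_by_name[drug].is_vehicle
        for r in range(1, config.replicates_per_timepoint + 1):
            # replicate 1 on the first array version, the rest on the second
            batch = batch_labels[min(r - 1, 1) % len(batch_labels)]
            shift, scale = config.batch_effects[batch]
            noise = rng.normal(0.0, config.noise_sd, size=config.n_probes)
            y = shift + scale * (mean_surface[(drug, t)].to_numpy() + noise)
            tag = f"{drug}_t{t:g}_r{r}"
            sample_ids.append(tag)
            rows.append((drug, t, r, batch, bool(is_vehicle)))
            data.append(y)

    values = pd.DataFrame(
        np.column_stack(data), index=probes, columns=pd.Index(sample_ids, name="sample_id")
    )
    sheet = pd.DataFrame(
        rows,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=["drug", "time_h", "replicate", "batch", "is_vehicle"],
    )
    truth = SyntheticTruth(
        network_membership=membership,
        A_true=A,
        B_true=B,
        mean_surface=mean_surface,
        vehicle_map=config.vehicle_map(),
    )
    return ExpressionMatrix(values=values, samples=sheet), truth


# ---------------------------------------------------------------------------
# Study-shaped default configurations
# ---------------------------------------------------------------------------

#: 13 pharmacological mechanisms (monoamine transporters and receptors)
STUDY_MECHANISMS = [
    "SERT", "NET", "DAT", "MAO", "HRH1", "HTR1A", "HTR2A", "HTR2C",
    "ADRA1A", "CHRM", "DRD2", "GABAA", "OPRM1",
]

# Target annotations of the 18-drug psychotropic panel (engagement 1.0 per
# listed target; values are synthetic — real binding affinities are
# user-supplied via ki_to_binding).
STUDY_DRUG_TARGETS: dict[str, list[str]] = {
    "mianserin": ["HRH1", "HTR2C", "HTR2A", "ADRA1A", "NET", "CHRM"],
    "imipramine": ["SERT", "HRH1", "NET", "ADRA1A", "HTR2C", "CHRM"],
    "fluoxetine": ["SERT", "NET", "HTR2C"],
    "bupropion": ["DAT"],
    "tianeptine": ["SERT", "NET", "DAT"],  # synthetic stand-in; unknown in vivo
    "tranylcypromine": ["MAO"],
    "methamphetamine": ["NET", "DAT"],
    "cocaine": ["DAT", "NET", "SERT"],
    "nicotine": ["DAT"],  # synthetic stand-in for n-AChR-driven dopamine release
    "heroin": ["OPRM1"],
    "morphine": ["OPRM1"],
    "ethanol": ["GABAA"],
    "diazepam": ["GABAA"],
    "buspirone": ["HTR1A"],
    "hydroxyzine": ["HRH1"],
    "clozapine": ["DRD2", "HRH1", "HTR2A", "HTR2C", "CHRM", "ADRA1A"],
    "risperidone": ["HTR2A", "HTR2C", "DRD2", "ADRA1A", "HRH1"],
    "haloperidol": ["DRD2", "HTR2A"],
}

TWEEN_DRUGS = {"risperidone", "haloperidol", "clozapine", "diazepam"}


#: default mechanism groups driving the three planted networks.  Each group
#: is engaged by a broad drug subset disjoint from the other groups' —
#: activity-dependent genes downstream of raised dopaminergic tone
#: (psychostimulants, MAO inhibition); genes responding to D2 and H1
#: blockade (antipsychotics, sedating antidepressants/antihistamines);
#: and an inhibitory-signaling network (GABA-A potentiation, opioid
#: receptor and 5-HT1A agonism, all Gi/Cl-coupled).  Breadth matters: a
#: co-expression module only shows a usable rank correlation when an
#: appreciable share of the drug panel drives it, and drug-disjointness
#: keeps the modules separable on the transcriptome map.
STUDY_NETWORK_MECHANISMS = (
    ("DAT", "MAO"),
    ("DRD2", "HRH1"),
    ("GABAA", "OPRM1", "HTR1A"),
)


def study_config(
    n_probes: int = 1000,
    network_sizes: tuple[int, ...] = (100, 40, 30),
    noise_sd: float = 0.3,
    seed: int = 0,
    **overrides,
) -> SyntheticConfig:
    """The 18-drug, 2-vehicle, 4-time-point, 3-replicate study design."""
    peaks = (1.0, 2.0, 4.0, 8.0)
    drugs = [
        DrugSpec(
            name=name,
            mechanisms={t: 1.0 for t in targets},
            control="tween" if name in TWEEN_DRUGS else "saline",
            peak_time_h=peaks[i % 4],
            amplitude=2.0,  # ~4-fold peak induction, typical of activity-dependent genes
        )
        for i, (name, targets) in enumerate(STUDY_DRUG_TARGETS.items())
    ]
    drugs.append(DrugSpec(name="saline", is_vehicle=True))
    drugs.append(DrugSpec(name="tween", is_vehicle=True))
    overrides.setdefault(
        "network_mechanisms", STUDY_NETWORK_MECHANISMS[: len(network_sizes)]
        if len(network_sizes) <= len(STUDY_NETWORK_MECHANISMS)
        else None,
    )
    return SyntheticConfig(
        n_probes=n_probes,
        mechanisms=list(STUDY_MECHANISMS),
        drugs=drugs,
        network_sizes=network_sizes,
        noise_sd=noise_sd,
        seed=seed,
        **overrides,
    )


def binding_fixture_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """14 drugs acting through at least one of 13 mechanisms.

    Mirrors the shape of a published drug × target binding panel; the
    engagement values themselves are synthetic.  Drops the drugs whose
    annotated targets fall outside the 13 mechanisms (or are unknown).
    """
    keep = [
        "mianserin", "imipramine", "fluoxetine", "bupropion", "tranylcypromine",
        "methamphetamine", "cocaine", "heroin", "morphine", "diazepam",
        "buspirone", "clozapine", "risperidone", "haloperidol",
    ]
    peaks = (1.0, 2.0, 4.0, 8.0)
    drugs = [
        DrugSpec(
            name=name,
            mechanisms={t: 1.0 for t in STUDY_DRUG_TARGETS[name]},
            control="tween" if name in TWEEN_DRUGS else "saline",
            peak_time_h=peaks[i % 4],
            amplitude=2.0,
        )
        for i, name in enumerate(keep)
    ]
    drugs.append(DrugSpec(name="saline", is_vehicle=True))
    drugs.append(DrugSpec(name="tween", is_vehicle=True))
    return SyntheticConfig(
        n_probes=overrides.pop("n_probes", 400),
        mechanisms=list(STUDY_MECHANISMS),
        drugs=drugs,
        seed=seed,
        **overrides,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_truth(truth: SyntheticTruth, outdir) -> None:
    """Write all ground-truth tables as TSV into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.network_membership.rename_axis("probe_id").to_csv(
        outdir / "truth_networks.tsv", sep="\t"
    )
    truth.A_true.rename_axis("mechanism").to_csv(outdir / "truth_A.tsv", sep="\t")
    truth.B_true.rename_axis("drug").to_csv(outdir / "truth_B.tsv", sep="\t")
    surf = truth.mean_surface.copy()
    surf.columns = [f"{d}_t{t:g}" for d, t in surf.columns]
    surf.rename_axis("probe_id").to_csv(outdir / "truth_mean_surface.tsv", sep="\t")


def write_config(config: SyntheticConfig, path) -> None:
    """Flat key-value dump of the generating configuration."""
    lines = [
        f"n_probes\t{config.n_probes}",
        f"mechanisms\t{','.join(config.mechanisms)}",
        f"network_sizes\t{','.join(map(str, config.network_sizes))}",
        f"time_points\t{','.join(map(str, config.time_points))}",
        f"replicates_per_timepoint\t{config.replicates_per_timepoint}",
        f"noise_sd\t{config.noise_sd}",
        f"frac_up\t{config.frac_up}",
        f"seed\t{config.seed}",
    ]
    for d in config.drugs:
        mech = ";".join(f"{m}:{v:g}" for m, v in d.mechanisms.items())
        lines.append(
            f"drug\t{d.name}\t{'vehicle' if d.is_vehicle else mech}"
            f"\t{d.control or '-'}\t{d.peak_time_h:g}\t{d.amplitude:g}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
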