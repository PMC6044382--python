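"""Synthetic LINCS-like fixtures with planted regulatory hierarchies.

The generator emulates the structure the pipeline consumes, at desk scale:
a landmark-gene universe, knockdown / overexpression / ligand records whose
z-score profiles flip a planted regulator's downstream programme (plus
Gaussian noise), same-name compound records mimicking the drug's effect (so
the ROC auto-cutoff path is exercisable), decoy compound records of pure
noise, and a matched treated/control query intensity table in which the
planted master regulator and its (direct and second-level) targets are DEGs.

Everything is a pure function of the spec, seed included, so fixtures are
reproducible byte for byte and no external download is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from indepth.errors import ValidationError
from indepth.query_signature import QuerySignature, call_degs, treatment_control_ratio
from indepth.reference_db import PerturbationRecord, ReferenceDB, write_reference


@dataclass(frozen=True)
class Regulator:
    """One planted regulator: its own drug response and the genes it drives.

    ``up_targets`` are positively regulated (regulator activity up pushes
    them up); ``down_targets`` negatively. ``effect_direction`` is the
    direction the regulator's own expression moves under the query drug and
    must be consistent with propagation from the level-1 regulators.
    """

    gene: str
    level: int
    effect_direction: str  # "up" | "down"
    up_targets: tuple[str, ...] = ()
    down_targets: tuple[str, ...] = ()


def _default_landmark(n: int) -> list[str]:
    return [f"G{i:03d}" for i in range(1, n + 1)]


def _default_regulators() -> tuple[Regulator, ...]:
    """Three-regulator hierarchy: a down-regulated master (G001) driving a
    down-regulated secondary regulator (G002) and an up-regulated one (G003)."""
    g = _default_landmark(200)
    return (
        Regulator(
            gene="G001", level=1, effect_direction="down",
            up_targets=("G002", *g[9:33]),    # G010..G033
            down_targets=("G003", *g[33:41]),  # G034..G041
        ),
        Regulator(gene="G002", level=2, effect_direction="down",
                  up_targets=tuple(g[49:61])),  # G050..G061
        Regulator(gene="G003", level=2, effect_direction="up",
                  up_targets=tuple(g[69:77])),  # G070..G077
    )


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Study conditions for one synthetic dataset."""

    n_landmark: int = 200
    regulators: tuple[Regulator, ...] = field(default_factory=_default_regulators)
    effect_z: float = 4.0          # mean |z| of a true target in a perturbation record
    noise_sd: float = 1.0          # sd of the null z-score background
    compound_noise_sd: float = 2.0  # extra variability of drug-treatment records
                                    # (dose/time/batch spread absent from clean
                                    # genetic perturbations)
    n_shrna_per_gene: int = 2      # independent shRNA clones per knocked-down gene
    n_compound_records: int = 3    # same-name compound records (ROC positives)
    n_decoy_compounds: int = 6     # noise-only compound records (ROC negatives)
    compound_name: str = "drugX"
    cell_line: str = "HT29"
    fold_change: float = 4.0       # planted treated/control ratio of a true DEG
    ratio_noise_sd: float = 0.1    # log-space sd of multiplicative ratio noise
    control_median: float = 400.0  # keeps floored intensities floor-free
    control_sd: float = 0.25       # log-space sd of control intensities
    seed: int = 0

    def __post_init__(self) -> None:
        landmark = set(self.landmark_genes)
        for reg in self.regulators:
            missing = (set(reg.up_targets) | set(reg.down_targets) | {reg.gene}) - landmark
            if missing:
                raise ValidationError(
                    f"regulator {reg.gene}: targets outside the landmark list: {sorted(missing)[:5]}"
                )
            if reg.effect_direction not in {"up", "down"}:
                raise ValidationError(f"regulator {reg.gene}: bad effect_direction")
        if self.n_shrna_per_gene < 2:
            raise ValidationError("n_shrna_per_gene must be >= 2 (off-target filter)")
        if not any(r.level == 1 for r in self.regulators):
            raise ValidationError("need at least one level-1 (master) regulator")

    @property
    def landmark_genes(self) -> list[str]:
        return _default_landmark(self.n_landmark)

    @property
    def master_regulator(self) -> str:
        return next(r.gene for r in self.regulators if r.level == 1)


def _propagated_effects(spec: PlantedNetworkSpec) -> dict[str, dict[str, float]]:
    """Per regulator: gene -> signed effect of raising that regulator's activity."""
    by_gene = {r.gene: r for r in spec.regulators}
    memo: dict[str, dict[str, float]] = {}

    def eff(reg: Regulator) -> dict[str, float]:
        if reg.gene in memo:
            return memo[reg.gene]
        out: dict[str, float] = {reg.gene: 1.0}
        for target, sign in [(t, 1.0) for t in reg.up_targets] + [
            (t, -1.0) for t in reg.down_targets
        ]:
            out[target] = out.get(target, 0.0) + sign
            if target in by_gene:
                for g2, s2 in eff(by_gene[target]).items():
                    if g2 != target:
                        out[g2] = out.get(g2, 0.0) + sign * s2
        memo[reg.gene] = out
        return out

    for reg in spec.regulators:
        eff(reg)
    return memo


def drug_effect(spec: PlantedNetworkSpec) -> dict[str, float]:
    """Signed drug effect per gene, propagated from the level-1 regulators."""
    effects = _propagated_effects(spec)
    out: dict[str, float] = {}
    for reg in spec.regulators:
        if reg.level != 1:
            continue
        direction = 1.0 if reg.effect_direction == "up" else -1.0
        for gene, s in effects[reg.gene].items():
            out[gene] = out.get(gene, 0.0) + direction * s
    for reg in spec.regulators:
        implied = out.get(reg.gene, 0.0)
        declared = 1.0 if reg.effect_direction == "up" else -1.0
        if implied and np.sign(implied) != declared:
            raise ValidationError(
                f"regulator {reg.gene}: effect_direction {reg.effect_direction!r} "
                f"contradicts propagation from level-1 regulators"
            )
    return out


def _planted_z(signs: dict[str, float], genes: list[str], amplitude: float) -> np.ndarray:
    z = np.zeros(len(genes))
    index = {g: i for i, g in enumerate(genes)}
    for gene, s in signs.items():
        if s:
            z[index[gene]] = amplitude * np.sign(s)
    return z


def generate_reference(spec: PlantedNetworkSpec) -> ReferenceDB:
    """Build the planted reference database (pure function of the spec)."""
    rng = np.random.default_rng([spec.seed, 0])
    genes = spec.landmark_genes
    n = spec.n_landmark
    effects = _propagated_effects(spec)
    records: list[PerturbationRecord] = []

    def noisy(planted: np.ndarray, sd: float | None = None) -> np.ndarray:
        return planted + rng.normal(0.0, sd if sd is not None else spec.noise_sd, n)

    for reg in spec.regulators:
        down_profile = _planted_z(effects[reg.gene], genes, -spec.effect_z)
        for k in range(1, spec.n_shrna_per_gene + 1):
            records.append(
                PerturbationRecord(
                    record_id=f"KD_{reg.gene}_{k}",
                    pert_id=f"sh_{reg.gene}_{k}",
                    pert_type="knockdown",
                    target_gene=reg.gene,
                    pert_name=f"sh{reg.gene}",
                    cell_line=spec.cell_line,
                    z=noisy(down_profile),
                )
            )
        if reg.effect_direction == "up":
            up_profile = _planted_z(effects[reg.gene], genes, spec.effect_z)
            for pert_type, prefix in (("overexpression", "OE"), ("ligand", "LIG")):
                records.append(
                    PerturbationRecord(
                        record_id=f"{prefix}_{reg.gene}",
                        pert_id=f"{prefix.lower()}_{reg.gene}",
                        pert_type=pert_type,
                        target_gene=reg.gene,
                        pert_name=f"{prefix.lower()}{reg.gene}",
                        cell_line=spec.cell_line,
                        z=noisy(up_profile),
                    )
                )
    drug_profile = _planted_z(drug_effect(spec), genes, spec.effect_z)
    for k in range(1, spec.n_compound_records + 1):
        records.append(
            PerturbationRecord(
                record_id=f"CP_{spec.compound_name}_{k}",
                pert_id=f"cp_{spec.compound_name}_{k}",
                pert_type="compound",
                target_gene=None,
                pert_name=spec.compound_name,
                cell_line=spec.cell_line,
                z=noisy(drug_profile, spec.compound_noise_sd),
            )
        )
    for k in range(1, spec.n_decoy_compounds + 1):
        records.append(
            PerturbationRecord(
                record_id=f"DCY_{k}",
                pert_id=f"cp_decoy_{k}",
                pert_type="compound",
                target_gene=None,
                pert_name=f"decoy{k}",
                cell_line=spec.cell_line,
                z=noisy(np.zeros(n), spec.compound_noise_sd),
            )
        )
    return ReferenceDB(landmark_genes=genes, records=records)


@dataclass(frozen=True)
class QueryFixture:
    """Generated query intensities plus the planted ground truth."""

    treated: pd.Series
    control: pd.Series
    ground_truth_gene: str
    true_up: frozenset[str]
    true_down: frozenset[str]

    def signature(self, drug_name: str) -> QuerySignature:
        ratios = treatment_control_ratio(self.treated, self.control)
        sig = call_degs(ratios, meta={"drug": drug_name})
        return sig


def generate_query(spec: PlantedNetworkSpec, noise_free: bool = False) -> QueryFixture:
    """Treated/control intensity tables whose DEGs recover the planted programme.

    Control intensities are lognormal; treated intensities multiply in the
    planted fold change (and, unless ``noise_free``, lognormal noise). The
    ground truth names the master regulator.
    """
    rng = np.random.default_rng([spec.seed, 1])
    genes = spec.landmark_genes
    n = spec.n_landmark
    effect = drug_effect(spec)
    control = spec.control_median * np.exp(rng.normal(0.0, spec.control_sd, n))
    fold = np.ones(n)
    index = {g: i for i, g in enumerate(genes)}
    for gene, s in effect.items():
        if s:
            fold[index[gene]] = spec.fold_change ** np.sign(s)
    noise = np.zeros(n) if noise_free else rng.normal(0.0, spec.ratio_noise_sd, n)
    treated = control * fold * np.exp(noise)
    gidx = pd.Index(genes, name="gene")
    return QueryFixture(
        treated=pd.Series(treated, index=gidx, name="treated"),
        control=pd.Series(control, index=gidx, name="control"),
        ground_truth_gene=spec.master_regulator,
        true_up=frozenset(g for g, s in effect.items() if s > 0),
        true_down=frozenset(g for g, s in effect.items() if s < 0),
    )


def write_fixture(spec: PlantedNetworkSpec, out_dir: str | Path) -> dict[str, Path]:
    """Emit the reference TSV triple, query table, and ground truth to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    db = generate_reference(spec)
    paths = write_reference(db, out_dir)
    fixture = generate_query(spec)
    query = pd.DataFrame({"treated": fixture.treated, "control": fixture.control})
    paths["query"] = out_dir / "query_expression.tsv"
    query.to_csv(paths["query"], sep="\t")
    truth = pd.DataFrame(
        {
            "gene": [fixture.ground_truth_gene],
            "role": ["master_regulator"],
            "compound_name": [spec.compound_name],
        }
    )
    paths["ground_truth"] = out_dir / "ground_truth.tsv"
    truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths
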