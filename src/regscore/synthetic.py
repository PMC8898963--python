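"""Synthetic cohort generator with known ground truth.

The generator emulates the latent structure the analysis pipeline assumes:
two sample subpopulations ("modification patterns") that differ in the mean
expression of a small regulator panel, two correlated downstream gene
programs (an immune program high in pattern 1 and a stemness program high in
pattern 2, optionally overlapping), background noise genes, and right-
censored exponential survival whose log-hazard is linear in the latent
pattern score. Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix, SignatureSet, SurvivalTable

__all__ = ["SyntheticTruth", "generate_cohort", "generate_survival",
           "generate_signatures"]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort.

    pattern maps each sample to latent class 1 or 2; ``z`` is the centered
    class score (-1/2 for pattern 1, +1/2 for pattern 2) that drives both the
    program factors and the survival hazard.
    """

    pattern: pd.Series                      # sample -> {1, 2}
    regulator_effect: dict[str, float]      # regulator gene -> mean shift delta
    program_genes: dict[str, list[str]]     # program name -> gene ids
    beta_surv: float = 0.0
    seed: int = 0
    program_sign: dict[str, float] = field(default_factory=dict)

    @property
    def z(self) -> pd.Series:
        return self.pattern.map({1: -0.5, 2: 0.5}).astype(float)

    def pattern_groups(self):
        from .data_model import GroupAssignment
        return GroupAssignment(self.pattern.astype(str))


def generate_cohort(
    n_samples: int,
    n_genes: int,
    n_regulators: int = 21,
    delta: float = 3.0,
    program_size: int = 50,
    overlap_frac: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    beta_surv: float = 0.0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a cohort with two latent patterns and two gene programs.

    Regulator genes get class means -/+ delta/2 by pattern plus
    N(0, noise_sd) noise; the shift direction alternates across the panel
    (even-indexed regulators up in pattern 2, odd-indexed down), the way a
    real writer/eraser/reader panel moves in both directions between
    modification patterns. Each program has a per-sample
    latent factor f = s * delta * z + N(0, 1) shared by its genes (sign
    s = -1 for the immune program, +1 for the stemness program, so the
    programs move in opposite directions across patterns); the unit-variance
    idiosyncratic part gives each program internal co-expression beyond the
    pattern signal, as co-regulated transcriptional programs show. Program
    genes are f + N(0, noise_sd). A fraction ``overlap_frac`` of each program's genes
    is shared between the two programs and loads on the average of the two
    factors. Remaining genes are pure N(0, noise_sd) noise.
    """
    if n_samples < 4:
        raise ValueError("need n_samples >= 4")
    if not (0.0 <= overlap_frac <= 1.0):
        raise ValueError("overlap_frac must lie in [0, 1]")
    n_overlap = int(round(overlap_frac * program_size))
    n_program_genes = 2 * program_size - n_overlap
    if n_genes < n_regulators + n_program_genes + 1:
        raise ValueError(
            f"n_genes={n_genes} too small for {n_regulators} regulators and "
            f"{n_program_genes} program genes"
        )

    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    pattern = np.ones(n_samples, dtype=int)
    pattern[n_samples // 2:] = 2
    rng.shuffle(pattern)
    z = np.where(pattern == 2, 0.5, -0.5)

    regulators = [f"REG{i + 1}" for i in range(n_regulators)]
    # disjoint unique parts + shared overlap genes
    n_unique = program_size - n_overlap
    immune = [f"IMM{i + 1}" for i in range(n_unique)]
    stem = [f"STEM{i + 1}" for i in range(n_unique)]
    shared = [f"OVL{i + 1}" for i in range(n_overlap)]
    n_noise = n_genes - n_regulators - len(immune) - len(stem) - len(shared)
    noise_genes = [f"G{i + 1}" for i in range(n_noise)]

    program_sign = {"immune": -1.0, "stemness": 1.0}
    f_imm = program_sign["immune"] * delta * z + rng.normal(0.0, 1.0, n_samples)
    f_stem = program_sign["stemness"] * delta * z + rng.normal(0.0, 1.0, n_samples)

    reg_sign = np.where(np.arange(n_regulators) % 2 == 0, 1.0, -1.0)
    blocks = []
    blocks.append(reg_sign[:, None] * delta * z[None, :]
                  + rng.normal(0.0, noise_sd, (n_regulators, n_samples)))
    blocks.append(f_imm[None, :] + rng.normal(0.0, noise_sd, (len(immune), n_samples)))
    blocks.append(f_stem[None, :] + rng.normal(0.0, noise_sd, (len(stem), n_samples)))
    if shared:
        f_shared = 0.5 * (f_imm + f_stem)
        blocks.append(f_shared[None, :] + rng.normal(0.0, noise_sd, (len(shared), n_samples)))
    blocks.append(rng.normal(0.0, noise_sd, (n_noise, n_samples)))

    gene_ids = regulators + immune + stem + shared + noise_genes
    data = pd.DataFrame(np.vstack(blocks), index=gene_ids, columns=sample_ids)

    truth = SyntheticTruth(
        pattern=pd.Series(pattern, index=sample_ids, name="pattern"),
        regulator_effect={g: float(s * delta)
                          for g, s in zip(regulators, reg_sign)},
        program_genes={"immune": immune + shared, "stemness": stem + shared},
        beta_surv=beta_surv,
        seed=seed,
        program_sign=program_sign,
    )
    return ExpressionMatrix(data), truth


def generate_survival(
    truth: SyntheticTruth,
    baseline_hazard: float = 0.01,
    censor_rate: float = 0.3,
    seed: int = 0,
) -> SurvivalTable:
    """Exponential event times with hazard h0 * exp(beta_surv * z).

    Censoring is independent exponential; its rate is tuned so the expected
    censored fraction matches ``censor_rate`` under the average event hazard
    (for two competing exponentials, P(censor first) = c / (c + h)).
    ``censor_rate=0`` disables censoring entirely.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be > 0")
    if not (0.0 <= censor_rate < 1.0):
        raise ValueError("censor_rate must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    z = truth.z.to_numpy()
    rate = baseline_hazard * np.exp(truth.beta_surv * z)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        mean_rate = float(np.mean(rate))
        c_rate = censor_rate / (1.0 - censor_rate) * mean_rate
        t_cens = rng.exponential(1.0 / c_rate, size=len(z))
    else:
        t_cens = np.full(len(z), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    df = pd.DataFrame({"time": time, "event": event}, index=truth.pattern.index)
    return SurvivalTable(df)


def generate_signatures(
    truth: SyntheticTruth,
    n_decoy_sets: int = 5,
    set_size: int = 30,
    seed: int = 0,
    gene_universe: list[str] | None = None,
) -> SignatureSet:
    """One signature per true program plus random decoy sets.

    Decoys draw ``set_size`` genes uniformly (without replacement) from the
    supplied universe after removing every program and regulator gene, so a
    decoy signature carries no pattern signal by construction. With no
    universe given, decoys are synthetic placeholder ids disjoint from all
    informative genes.
    """
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    category: dict[str, str | None] = {}
    for name, genes in truth.program_genes.items():
        sets[f"sig_{name}"] = list(genes)
        category[f"sig_{name}"] = "program"
    informative = ({g for gl in truth.program_genes.values() for g in gl}
                   | set(truth.regulator_effect))
    if gene_universe is None:
        universe = [f"G{i + 1}" for i in range(max(10 * set_size, 100))]
    else:
        universe = [g for g in gene_universe if g not in informative]
    if n_decoy_sets > 0 and set_size > len(universe):
        raise ValueError("set_size exceeds gene universe")
    for i in range(n_decoy_sets):
        picked = rng.choice(len(universe), size=set_size, replace=False)
        name = f"decoy_{i + 1}"
        sets[name] = [universe[j] for j in sorted(picked)]
        category[name] = "decoy"
    return SignatureSet("synthetic_signatures", sets, category)
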