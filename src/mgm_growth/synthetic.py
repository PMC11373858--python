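"""Synthetic rearing-experiment generator.

Emulates an individual-rearing growth experiment on house crickets: nymphs
weighed and fed twice a week for 72 days at constant temperature, with food
provided in excess (ad libitum), food-plus-faeces remains recovered at each
occasion, faeces separated and weighed on some occasions, and age at imago
emergence recorded.

Each individual carries lognormal random-effect multipliers (mean 1) on a
configurable subset of parameters, so the population has the hierarchical
structure the calibration pipeline assumes: allometric exponents shared,
normalization constants varying between individuals.

The latent growth trajectory follows the resting-metabolism form of the
growth equation, ``dW/dt = (a_R*W**b_R - R_M(W))/E_S``, so the resting
power allometry holds exactly; ingestion follows the broken power allometry
exactly; feeding costs are implied by the energy balance and are summarized
by their hockey-stick projection over the rising-ingestion phase
(W <= W_star, where S(W) is single-valued; the values stored in the
templates).
This places the model's one structural approximation in the feeding-cost
component, where the analysis treats it as an empirical relation anyway.

Mass bookkeeping per feeding interval (all masses mg):

* ``consumed_dry = (ingested energy)/E_f`` with ingested energy the
  integral of S(W(t)) over the interval along the individual's trajectory;
* faecal dry output is a fraction ``r`` of consumed dry mass;
* recovered remains (food + faeces unless separated) take up moisture:
  as-weighed mass = dry mass × (1 + m);
* every weighing gets multiplicative Gaussian noise with a common CV.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MGMParams
from .simulate import Trajectory, integrate_growth

__all__ = [
    "Individual",
    "ObservationModel",
    "DEFAULT_MALE",
    "DEFAULT_FEMALE",
    "DEFAULT_RE_SPEC",
    "default_schedule",
    "generate_population",
    "simulate_experiment",
    "generate_dataset",
]

# Sex-specific parameter templates for the synthetic cricket population.
# Units: mass mg fresh weight, energy J, time days.  The feeding-cost
# values (S1, kF1, kF2) are the hockey-stick projection of the feeding
# costs implied by the energy balance along the template trajectory.
DEFAULT_FEMALE = MGMParams(
    sex="female",
    e=0.8,
    E_M=6.0,
    E_S=2.7,
    alpha=4.0,
    beta=0.8,
    k=0.016,
    W_star=560.0,
    W_mat=440.0,
    S1=327.33,
    kF1=0.090567,
    kF2=0.499218,
    gamma_BS=0.15,
    gamma_BR=0.26,
    a_N=0.0012,
    a_R=0.75,
    b_R=0.9,
    W_0=2.0,
)

DEFAULT_MALE = MGMParams(
    sex="male",
    e=0.8,
    E_M=6.0,
    E_S=2.7,
    alpha=4.0,
    beta=0.8,
    k=0.016,
    W_star=480.0,
    W_mat=380.0,
    S1=339.98,
    kF1=0.134921,
    kF2=0.531681,
    gamma_B=0.18,
    a_N=0.0010,
    a_R=0.75,
    b_R=0.9,
    W_0=2.0,
)

# Random effects: lognormal multipliers (mean 1) on normalization-type
# parameters; exponents are shared across individuals.  "gamma" targets the
# sex-appropriate basal coefficient (gamma_B males, gamma_BS females).
DEFAULT_RE_SPEC: dict[str, float] = {
    "alpha": 0.15,
    "gamma": 0.15,
    "W_mat": 0.15,
    "W_0": 0.15,
}


def default_schedule(t_end: float = 72.0, spacing: float = 3.5) -> np.ndarray:
    """Twice-weekly measurement occasions from day 0 through ``t_end``."""
    return np.arange(0.0, t_end + 1e-9, spacing)


@dataclass(frozen=True)
class ObservationModel:
    """Measurement-process parameters of the synthetic experiment.

    These are invented emulation defaults, not literature estimates: a 3%
    weighing CV, 15% moisture uptake in remains, an egestion fraction tied
    to the assimilation efficiency (equal energy density of food and
    faeces assumed), and faeces separated every 4th occasion.
    """

    weighing_cv: float = 0.03
    moisture_uptake: float = 0.15     # m: as-weighed = dry*(1+m)
    egestion_fraction: float | None = None  # r; default 1 - e of the template
    E_f: float = 17.0                  # food energy density, J/mg dry
    separation_period: int = 4         # faeces separated every k-th occasion
    provision_factor: float = 1.6      # provided = factor*consumed + floor
    provision_floor: float = 50.0      # mg dry, keeps early rations ad libitum

    def __post_init__(self) -> None:
        if self.weighing_cv < 0 or self.moisture_uptake < 0:
            raise ValueError("observation-model parameters must be nonnegative")
        if self.egestion_fraction is not None and not (0 <= self.egestion_fraction < 1):
            raise ValueError("egestion fraction must lie in [0, 1)")
        if self.E_f <= 0:
            raise ValueError("food energy density must be positive")

    def resolve_r(self, p: MGMParams) -> float:
        return self.egestion_fraction if self.egestion_fraction is not None else 1.0 - p.e


@dataclass
class Individual:
    """One synthetic animal: identity, sex and realized parameters."""

    id: str
    sex: str
    multipliers: dict[str, float]
    params: MGMParams
    maturity_age: float | None = None  # filled once the trajectory is known

    @property
    def W_mat(self) -> float:
        return self.params.W_mat

    @property
    def W_0(self) -> float:
        return self.params.W_0


def _apply_multipliers(template: MGMParams, mult: dict[str, float]) -> MGMParams:
    changes: dict[str, float] = {}
    for name, m in mult.items():
        if name == "gamma":
            if template.sex == "male":
                changes["gamma_B"] = template.gamma_B * m
            else:
                changes["gamma_BS"] = template.gamma_BS * m
        elif name == "W_mat":
            # scale the ingestion peak with maturity mass to preserve the
            # geometry of the adult ingestion branch
            changes["W_mat"] = template.W_mat * m
            changes["W_star"] = template.W_star * m
        else:
            changes[name] = getattr(template, name) * m
    return template.replace(**changes)


def generate_population(
    n_male: int = 14,
    n_female: int = 21,
    male_template: MGMParams = DEFAULT_MALE,
    female_template: MGMParams = DEFAULT_FEMALE,
    re_spec: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> list[Individual]:
    """Draw a population of individuals with lognormal random effects.

    ``re_spec`` maps parameter names to log-scale SDs; multipliers are
    lognormal with mean exactly 1 (log-mean ``-sd**2/2``).  All SDs zero
    reproduces the templates.  A fixed seed gives a reproducible
    population.
    """
    if re_spec is None:
        re_spec = DEFAULT_RE_SPEC
    if any(sd < 0 for sd in re_spec.values()):
        raise ValueError("random-effect SDs must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop: list[Individual] = []
    for sex, n, template in (("male", n_male, male_template), ("female", n_female, female_template)):
        for i in range(n):
            mult = {
                name: float(np.exp(rng.normal(-0.5 * sd**2, sd)))
                for name, sd in re_spec.items()
            }
            pop.append(
                Individual(
                    id=f"{sex[0].upper()}{i + 1:02d}",
                    sex=sex,
                    multipliers=mult,
                    params=_apply_multipliers(template, mult),
                )
            )
    return pop


def _latent_trajectory(ind: Individual, t_end: float) -> Trajectory:
    return integrate_growth(
        ind.params, (0.0, t_end), form="resting",
        t_eval=np.linspace(0.0, t_end, 289),
    )


def simulate_experiment(
    pop: list[Individual],
    schedule: np.ndarray | None = None,
    obs_model: ObservationModel | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Run the virtual experiment and return the raw occasion table.

    Columns: individual id, sex, occasion index, age (days), measured body
    mass (mg), food provided (mg dry), food+faeces recovered (mg
    as-weighed), separated faeces (mg as-weighed, on designated occasions),
    imago flag.
    """
    if schedule is None:
        schedule = default_schedule()
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size < 2 or np.any(np.diff(schedule) <= 0):
        raise ValueError("schedule must contain at least two strictly increasing ages")
    if obs_model is None:
        obs_model = ObservationModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cv = obs_model.weighing_cv
    m = obs_model.moisture_uptake

    def weigh(x: float) -> float:
        return float(x * (1.0 + cv * rng.standard_normal())) if cv > 0 else float(x)

    rows = []
    for ind in pop:
        traj = _latent_trajectory(ind, float(schedule[-1]))
        ind.maturity_age = traj.maturity_age
        r = obs_model.resolve_r(ind.params)
        W_true = traj.mass_at(schedule)
        for j, age in enumerate(schedule):
            row = {
                "id": ind.id,
                "sex": ind.sex,
                "occasion": j,
                "age_d": float(age),
                "mass_mg": weigh(W_true[j] if schedule.size > 1 else W_true),
                "imago": bool(
                    ind.maturity_age is not None and age >= ind.maturity_age
                ),
                "provided_mg": np.nan,
                "recovered_mg": np.nan,
                "faeces_mg": np.nan,
            }
            if j < schedule.size - 1:
                energy = traj.ingestion_integral(schedule[j], schedule[j + 1])
                consumed = energy / obs_model.E_f  # dry mg
                provided = obs_model.provision_factor * consumed + obs_model.provision_floor
                recovered_dry = provided - consumed + r * consumed
                row["provided_mg"] = weigh(provided)
                row["recovered_mg"] = weigh(recovered_dry * (1.0 + m))
                separated = (
                    obs_model.separation_period > 0
                    and (j + 1) % obs_model.separation_period == 0
                )
                if separated:
                    row["faeces_mg"] = weigh(r * consumed * (1.0 + m))
            rows.append(row)
    df = pd.DataFrame(rows)
    return df[
        ["id", "sex", "occasion", "age_d", "mass_mg", "provided_mg",
         "recovered_mg", "faeces_mg", "imago"]
    ]


def generate_dataset(
    seed: int = 0,
    n_male: int = 17,
    n_female: int = 25,
    attrition: int = 7,
    re_spec: dict[str, float] | None = None,
    obs_model: ObservationModel | None = None,
    schedule: np.ndarray | None = None,
    male_template: MGMParams = DEFAULT_MALE,
    female_template: MGMParams = DEFAULT_FEMALE,
) -> tuple[pd.DataFrame, dict]:
    """Full experiment with attrition: rear 42 nymphs, keep 35 usable.

    Default sizes mirror the emulated study design: 42 individuals reared,
    7 lost, leaving 14 males and 21 females.  Returns the raw table and a
    truth-metadata dict (seed, templates, observation model, per-individual
    multipliers and maturity ages) for recovery scoring.
    """
    rng = np.random.default_rng(seed)
    pop = generate_population(
        n_male, n_female, male_template, female_template, re_spec, rng
    )
    if attrition > 0:
        # drop 3 males + 4 females (or proportionally for other sizes)
        n_drop_m = round(attrition * n_male / (n_male + n_female))
        n_drop_f = attrition - n_drop_m
        males = [i for i in pop if i.sex == "male"]
        females = [i for i in pop if i.sex == "female"]
        drop = set(
            rng.choice([i.id for i in males], n_drop_m, replace=False)
        ) | set(rng.choice([i.id for i in females], n_drop_f, replace=False))
        pop = [i for i in pop if i.id not in drop]
    raw = simulate_experiment(pop, schedule, obs_model, rng)
    obs = obs_model if obs_model is not None else ObservationModel()
    meta = {
        "seed": seed,
        "n_usable": len(pop),
        "obs_model": dataclasses.asdict(obs),
        "templates": {
            "male": male_template.to_dict(),
            "female": female_template.to_dict(),
        },
        "re_spec": dict(re_spec if re_spec is not None else DEFAULT_RE_SPEC),
        "individuals": {
            ind.id: {
                "sex": ind.sex,
                "multipliers": ind.multipliers,
                "W_mat": ind.W_mat,
                "W_0": ind.W_0,
                "maturity_age": ind.maturity_age,
            }
            for ind in pop
        },
    }
    return raw, meta


def save_dataset(raw: pd.DataFrame, meta: dict, table_path, meta_path) -> None:
    """Write the raw table as CSV and the truth metadata as JSON."""
    with open(table_path, "w") as fh:
        fh.write(
            "# synthetic rearing experiment; age_d [day], mass_mg [mg fresh], "
            "provided_mg [mg dry], recovered_mg/faeces_mg [mg as-weighed]\n"
        )
        raw.to_csv(fh, index=False)
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1)
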