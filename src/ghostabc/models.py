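"""Demographic models of archaic "ghost" admixture into African populations.

Six nested models of human demography are encoded as parameterised event
lists over a fixed seven-genome panel (Altai Neanderthal ``N``, Denisovan
``D``, East Asian ``EAs``, European ``Eu``, West African ``WAf``, Mbuti
``Mbt``, Khoisan ``Kho``) plus unsampled lineages:

* ``A`` — baseline: Neanderthal/Denisovan archaic clade, early-human gene
  flow into Neanderthals, a deep ghost ``Xe`` contributing to Denisovans,
  Khoisan at the root of modern humans, the out-of-Africa split,
  Neanderthal-like introgression into Eurasians, Denisovan-like
  introgression into East Asians, and recent migrations among Europeans,
  West Africans, Mbuti and Khoisan.
* ``B`` — adds a basal modern-human ghost ``XAf`` that pulses independently
  into West Africans, Mbuti and Khoisan.
* ``C`` — instead adds a Neanderthal-lineage ghost ``Xn`` branching off the
  sampled Neanderthal branch (after the Neanderthal-Denisovan split).
* ``D`` — ``Xn`` branches from the archaic stem before the
  Neanderthal-Denisovan split.
* ``E`` — both ghosts of B and C.
* ``F`` — both ghosts of B and D.

Times are carried in kya and converted to generations with a configurable
generation time (default 29 years). Population sizes are diploid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Mapping

import numpy as np

__all__ = [
    "Pop",
    "DemographicEvent",
    "DemographicModel",
    "Prior",
    "MissingParameterError",
    "TopologyError",
    "MODEL_IDS",
    "GENERATION_TIME",
    "enumerate_parameters",
    "default_priors",
    "draw_parameters",
    "build_model",
]

GENERATION_TIME = 29.0  # years per generation for time scaling

MODEL_IDS = ("A", "B", "C", "D", "E", "F")


class Pop(str, Enum):
    """Panel members, ghost lineages and the outgroup."""

    EAS = "EAs"
    EU = "Eu"
    WAF = "WAf"
    MBT = "Mbt"
    KHO = "Kho"
    N = "N"
    NI = "NI"
    D = "D"
    DI = "DI"
    XE = "Xe"
    XAF = "XAf"
    XN = "Xn"
    CHIMP = "Chimp"  # outgroup for polarisation only; never simulated


#: Panel sample order used everywhere downstream (jSFS axis order).
PANEL = ("N", "D", "EAs", "Eu", "WAf", "Mbt", "Kho")

# Ancestral (internal-branch) populations; names reflect their descendants.
ANC_EUR = "AncEur"            # EAs + Eu
ANC_OOA = "AncOOA"            # WAf + Eurasians
ANC_MBT = "AncMbt"            # Mbt + the above
ANC_AMH = "AncAMH"            # Kho + the above (modern-human stem)
ANC_ND = "AncND"              # Neanderthal + Denisovan stem
ANC_AMH_XAF = "AncAMHXAf"     # modern-human stem + XAf (models B, E, F)
ANC_HOMININ = "AncHominin"    # modern-human side + archaic side
ANC_ROOT = "AncRoot"          # the above + the deep ghost Xe


class MissingParameterError(KeyError):
    """A model was built without one of its required free parameters."""


class TopologyError(ValueError):
    """Event times violate the model topology (e.g. a pulse after a merge)."""


@dataclass(frozen=True)
class DemographicEvent:
    """One timed event in a demographic model.

    ``kind`` is one of ``split`` (forward-in-time: ``source`` splits from
    ``dest``), ``pulse_introgression`` (forward: a fraction ``magnitude`` of
    ``dest`` is replaced by migrants from ``source``),
    ``continuous_migration`` (forward donor ``source`` -> recipient ``dest``
    at rate ``magnitude`` per generation, active from ``time`` to the
    present) and ``size_change``.
    """

    kind: str
    time: float  # generations before present
    source: str
    dest: str
    magnitude: float = 0.0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if self.kind == "pulse_introgression" and not 0.0 <= self.magnitude <= 1.0:
            raise ValueError("pulse proportion must be in [0, 1]")


@dataclass
class DemographicModel:
    """A fully resolved demographic model ready for simulation."""

    model_id: str
    populations: dict[str, float]  # name -> diploid size
    events: list[DemographicEvent]
    generation_time: float = GENERATION_TIME
    sample_ages: dict[str, float] = field(default_factory=dict)  # generations
    params: dict[str, float] = field(default_factory=dict)

    def events_of(self, kind: str) -> list[DemographicEvent]:
        return [e for e in self.events if e.kind == kind]


@dataclass(frozen=True)
class Prior:
    """A univariate prior: ``uniform`` or ``log-uniform`` on [low, high)."""

    family: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"prior requires low < high, got [{self.low}, {self.high}]")
        if self.family not in ("uniform", "log-uniform"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.family == "log-uniform" and self.low <= 0:
            raise ValueError("log-uniform prior requires low > 0")

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family == "uniform":
            return rng.uniform(self.low, self.high, size=size)
        return np.exp(rng.uniform(np.log(self.low), np.log(self.high), size=size))


def _kya_to_gen(t_kya: float, generation_time: float) -> float:
    return t_kya * 1000.0 / generation_time


# ---------------------------------------------------------------------------
# Parameter enumeration
# ---------------------------------------------------------------------------

_BASE_TIMES = [
    "tAMH_Archaics",
    "tN_D",
    "tAMH",
    "tMbt",
    "tOOA",
    "tEAs_Eu",
    "tN_NI",
    "tD_DI",
    "tXe",
    "tMigrationOnset",
]

_BASE_PULSES = [
    "IntrogressionDI_Han",
    "IntrogressionEarlyHumans_Neanderthal",
    "IntrogressionNI_Eurasia",
    "IntrogressionXe_Denisovan",
]

_BASE_PULSE_TIMES = [
    "tIntrogressionDI_Han",
    "tIntrogressionEarlyHumans_Neanderthal",
    "tIntrogressionNI_Eurasia",
    "tIntrogressionXe_Denisovan",
]

#: Forward-time recent migrations, donor -> recipient.
MIGRATION_PAIRS = [
    ("Eu", "WAf"),
    ("Eu", "Mbt"),
    ("Eu", "Kho"),
    ("WAf", "Mbt"),
    ("WAf", "Kho"),
    ("Mbt", "WAf"),
    ("Mbt", "Kho"),
    ("Kho", "Mbt"),
]

_BASE_MIGRATIONS = [f"m{a}_{b}" for a, b in MIGRATION_PAIRS]

_BASE_SIZES = [
    "N_EAs",
    "N_Eu",
    "N_WAf",
    "N_Mbt",
    "N_Kho",
    "N_N",
    "N_NI",
    "N_D",
    "N_DI",
    "N_Xe",
    "N_AncEur",
    "N_AncOOA",
    "N_AncMbt",
    "N_AncAMH",
    "N_AncND",
    "N_AncHominin",
    "N_AncRoot",
]

_XAF_BLOCK = [
    "tAMH_XAf",
    "IntrogressionXf_Kho",
    "IntrogressionXf_Mbuti",
    "IntrogressionXf_WestAfrica",
    "tIntrogressionXf_Kho",
    "tIntrogressionXf_Mbuti",
    "tIntrogressionXf_WestAfrica",
    "N_XAf",
    "N_AncAMHXAf",
]

_XN_BLOCK = [
    "tXn",
    "IntrogressionXn_Kho",
    "IntrogressionXn_Mbuti",
    "IntrogressionXn_WestAfrica",
    "tIntrogressionXn_Kho",
    "tIntrogressionXn_Mbuti",
    "tIntrogressionXn_WestAfrica",
    "N_Xn",
]


def _check_model_id(model_id: str) -> str:
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}; expected one of {MODEL_IDS}")
    return model_id


def enumerate_parameters(model_id: str) -> list[str]:
    """Return the ordered names of the free parameters of a model.

    The order is stable: split/onset times, pulse proportions, pulse times,
    recent-migration rates, then diploid sizes. Model B exposes 52 free
    parameters; model A the 43 shared ones.
    """
    _check_model_id(model_id)
    names = list(_BASE_TIMES)
    pulses = list(_BASE_PULSES)
    pulse_times = list(_BASE_PULSE_TIMES)
    sizes = list(_BASE_SIZES)
    if model_id in ("B", "E", "F"):
        names.insert(1, "tAMH_XAf")
        pulses += ["IntrogressionXf_Kho", "IntrogressionXf_Mbuti", "IntrogressionXf_WestAfrica"]
        pulse_times += [
            "tIntrogressionXf_Kho",
            "tIntrogressionXf_Mbuti",
            "tIntrogressionXf_WestAfrica",
        ]
        sizes += ["N_XAf", "N_AncAMHXAf"]
    if model_id in ("C", "D", "E", "F"):
        names.append("tXn")
        pulses += ["IntrogressionXn_Kho", "IntrogressionXn_Mbuti", "IntrogressionXn_WestAfrica"]
        pulse_times += [
            "tIntrogressionXn_Kho",
            "tIntrogressionXn_Mbuti",
            "tIntrogressionXn_WestAfrica",
        ]
        sizes += ["N_Xn"]
    return names + pulses + pulse_times + _BASE_MIGRATIONS + sizes


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

def default_priors(model_id: str) -> dict[str, Prior]:
    """Shipped default priors for a model.

    The exact prior table used in the original study is not public; these
    are reconstructions — wide uniforms chosen so that published posterior
    95% credible intervals of model B fall inside them. Treat them as
    configuration, not as fixed truth.
    """
    _check_model_id(model_id)
    p: dict[str, Prior] = {
        "tAMH_Archaics": Prior("uniform", 400, 1000, "kya"),
        "tN_D": Prior("uniform", 250, 600, "kya"),
        "tAMH": Prior("uniform", 100, 300, "kya"),
        "tMbt": Prior("uniform", 80, 180, "kya"),
        "tOOA": Prior("uniform", 60, 100, "kya"),
        "tEAs_Eu": Prior("uniform", 30, 45, "kya"),
        "tN_NI": Prior("uniform", 80, 250, "kya"),
        "tD_DI": Prior("uniform", 80, 250, "kya"),
        "tXe": Prior("uniform", 1000, 2500, "kya"),
        "tMigrationOnset": Prior("uniform", 1, 25, "kya"),
        "IntrogressionDI_Han": Prior("uniform", 0.0, 0.1, "proportion"),
        "IntrogressionEarlyHumans_Neanderthal": Prior("uniform", 0.0, 0.1, "proportion"),
        "IntrogressionNI_Eurasia": Prior("uniform", 0.0, 0.1, "proportion"),
        "IntrogressionXe_Denisovan": Prior("uniform", 0.0, 0.1, "proportion"),
        "tIntrogressionDI_Han": Prior("uniform", 15, 29, "kya"),
        "tIntrogressionEarlyHumans_Neanderthal": Prior("uniform", 150, 280, "kya"),
        "tIntrogressionNI_Eurasia": Prior("uniform", 46, 59, "kya"),
        "tIntrogressionXe_Denisovan": Prior("uniform", 100, 240, "kya"),
    }
    for name in _BASE_MIGRATIONS:
        p[name] = Prior("uniform", 0.0, 1e-4, "per generation")
    for name in ("N_EAs", "N_Eu", "N_WAf", "N_Mbt", "N_Kho"):
        p[name] = Prior("uniform", 5_000, 40_000, "diploid")
    for name in ("N_N", "N_NI", "N_D", "N_DI", "N_Xe"):
        p[name] = Prior("uniform", 1_000, 20_000, "diploid")
    for name in ("N_AncEur", "N_AncOOA", "N_AncMbt", "N_AncAMH", "N_AncND",
                 "N_AncHominin", "N_AncRoot"):
        p[name] = Prior("uniform", 5_000, 30_000, "diploid")
    if model_id in ("B", "E", "F"):
        p["tAMH_XAf"] = Prior("uniform", 150, 800, "kya")
        for name in ("IntrogressionXf_Kho", "IntrogressionXf_Mbuti",
                     "IntrogressionXf_WestAfrica"):
            p[name] = Prior("uniform", 0.0, 0.1, "proportion")
        for name in ("tIntrogressionXf_Kho", "tIntrogressionXf_Mbuti",
                     "tIntrogressionXf_WestAfrica"):
            p[name] = Prior("uniform", 5, 45, "kya")
        p["N_XAf"] = Prior("uniform", 1_000, 20_000, "diploid")
        p["N_AncAMHXAf"] = Prior("uniform", 5_000, 30_000, "diploid")
    if model_id in ("C", "D", "E", "F"):
        # Xn hangs off the Neanderthal branch (C, E) or off the archaic stem
        # before the N-D split (D, F); its split-time prior differs.
        if model_id in ("C", "E"):
            p["tXn"] = Prior("uniform", 150, 400, "kya")
        else:
            p["tXn"] = Prior("uniform", 450, 900, "kya")
        for name in ("IntrogressionXn_Kho", "IntrogressionXn_Mbuti",
                     "IntrogressionXn_WestAfrica"):
            p[name] = Prior("uniform", 0.0, 0.1, "proportion")
        for name in ("tIntrogressionXn_Kho", "tIntrogressionXn_Mbuti",
                     "tIntrogressionXn_WestAfrica"):
            p[name] = Prior("uniform", 5, 45, "kya")
        p["N_Xn"] = Prior("uniform", 1_000, 20_000, "diploid")
    return {name: p[name] for name in enumerate_parameters(model_id)}


# ---------------------------------------------------------------------------
# Topology validation
# ---------------------------------------------------------------------------

def _ordering_violation(
    model_id: str,
    q: Mapping[str, float],
    sample_age_N: float,
    sample_age_D: float,
) -> str | None:
    """Return a description of the first violated ordering, or None."""
    checks: list[tuple[bool, str]] = [
        (q["tEAs_Eu"] < q["tOOA"], "tEAs_Eu < tOOA"),
        (q["tOOA"] < q["tMbt"], "tOOA < tMbt"),
        (q["tMbt"] < q["tAMH"], "tMbt < tAMH"),
        (q["tAMH"] < q["tAMH_Archaics"], "tAMH < tAMH_Archaics"),
        (q["tN_D"] < q["tAMH_Archaics"], "tN_D < tAMH_Archaics"),
        (q["tN_NI"] < q["tN_D"], "tN_NI < tN_D"),
        (q["tD_DI"] < q["tN_D"], "tD_DI < tN_D"),
        (q["tXe"] > q["tAMH_Archaics"], "tXe > tAMH_Archaics"),
        (q["tMigrationOnset"] < q["tEAs_Eu"], "tMigrationOnset < tEAs_Eu"),
        (
            q["tIntrogressionDI_Han"] < min(q["tEAs_Eu"], q["tD_DI"]),
            "tIntrogressionDI_Han < min(tEAs_Eu, tD_DI)",
        ),
        (
            q["tEAs_Eu"] < q["tIntrogressionNI_Eurasia"] < min(q["tOOA"], q["tN_NI"]),
            "tEAs_Eu < tIntrogressionNI_Eurasia < min(tOOA, tN_NI)",
        ),
        (
            max(q["tAMH"], sample_age_N)
            < q["tIntrogressionEarlyHumans_Neanderthal"]
            < q["tN_D"],
            "max(tAMH, N sampling age) < tIntrogressionEarlyHumans_Neanderthal < tN_D",
        ),
        (
            sample_age_D < q["tIntrogressionXe_Denisovan"] < q["tN_D"],
            "D sampling age < tIntrogressionXe_Denisovan < tN_D",
        ),
    ]
    if model_id in ("B", "E", "F"):
        checks += [
            (q["tAMH"] < q["tAMH_XAf"] < q["tAMH_Archaics"],
             "tAMH < tAMH_XAf < tAMH_Archaics"),
            (q["tIntrogressionXf_WestAfrica"] < min(q["tOOA"], q["tAMH_XAf"]),
             "tIntrogressionXf_WestAfrica < min(tOOA, tAMH_XAf)"),
            (q["tIntrogressionXf_Mbuti"] < min(q["tMbt"], q["tAMH_XAf"]),
             "tIntrogressionXf_Mbuti < min(tMbt, tAMH_XAf)"),
            (q["tIntrogressionXf_Kho"] < min(q["tAMH"], q["tAMH_XAf"]),
             "tIntrogressionXf_Kho < min(tAMH, tAMH_XAf)"),
        ]
    if model_id in ("C", "E"):
        checks.append((q["tXn"] < q["tN_D"], "tXn < tN_D (Xn on the Neanderthal branch)"))
    if model_id in ("D", "F"):
        checks.append(
            (q["tN_D"] < q["tXn"] < q["tAMH_Archaics"],
             "tN_D < tXn < tAMH_Archaics (Xn on the archaic stem)")
        )
    if model_id in ("C", "D", "E", "F"):
        checks += [
            (q["tIntrogressionXn_WestAfrica"] < min(q["tOOA"], q["tXn"]),
             "tIntrogressionXn_WestAfrica < min(tOOA, tXn)"),
            (q["tIntrogressionXn_Mbuti"] < min(q["tMbt"], q["tXn"]),
             "tIntrogressionXn_Mbuti < min(tMbt, tXn)"),
            (q["tIntrogressionXn_Kho"] < min(q["tAMH"], q["tXn"]),
             "tIntrogressionXn_Kho < min(tAMH, tXn)"),
        ]
    for ok, desc in checks:
        if not ok:
            return desc
    return None


# ---------------------------------------------------------------------------
# Drawing from priors
# ---------------------------------------------------------------------------

def draw_parameters(
    priors: Mapping[str, Prior],
    model_id: str,
    rng_seed: int | np.random.Generator,
    *,
    sample_age_N: float = 120.0,
    sample_age_D: float = 70.0,
    max_attempts: int = 1000,
) -> dict[str, float]:
    """Draw one topologically consistent parameter vector from the priors.

    Draws violating the model's event-time orderings are rejected and
    redrawn (whole-vector rejection), which is unbiased on the constrained
    region. Raises after ``max_attempts`` consecutive rejections.
    """
    _check_model_id(model_id)
    required = enumerate_parameters(model_id)
    missing = [n for n in required if n not in priors]
    if missing:
        raise MissingParameterError(f"priors missing for parameters: {missing}")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    last = ""
    for _ in range(max_attempts):
        draw = {name: float(priors[name].sample(rng)) for name in required}
        bad = _ordering_violation(model_id, draw, sample_age_N, sample_age_D)
        if bad is None:
            return draw
        last = bad
    raise TopologyError(
        f"could not draw a consistent parameter vector for model {model_id} in "
        f"{max_attempts} attempts; last violated constraint: {last}"
    )


# ---------------------------------------------------------------------------
# Building the resolved event list
# ---------------------------------------------------------------------------

def build_model(
    model_id: str,
    params: Mapping[str, float],
    *,
    generation_time: float = GENERATION_TIME,
    sample_age_N: float = 120.0,
    sample_age_D: float = 70.0,
) -> DemographicModel:
    """Resolve a model id plus parameter vector into a timed event list.

    ``sample_age_N`` / ``sample_age_D`` are the assumed ages (kya) of the
    Neanderthal and Denisovan genomes; they are configuration, not free
    parameters. Deterministic given its inputs.
    """
    _check_model_id(model_id)
    required = enumerate_parameters(model_id)
    missing = [n for n in required if n not in params]
    if missing:
        raise MissingParameterError(f"model {model_id} missing parameters: {missing}")
    q = {n: float(params[n]) for n in required}
    for name, value in q.items():
        if name.startswith("Introgression") and not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value}")
        if name.startswith(("t", "N_", "m")) and value < 0:
            raise ValueError(f"{name} must be >= 0, got {value}")
    bad = _ordering_violation(model_id, q, sample_age_N, sample_age_D)
    if bad is not None:
        raise TopologyError(f"model {model_id}: ordering constraint violated: {bad}")

    g = lambda t: _kya_to_gen(t, generation_time)  # noqa: E731

    populations = {name[2:]: q[name] for name in required if name.startswith("N_")}
    has_xaf = model_id in ("B", "E", "F")
    has_xn = model_id in ("C", "D", "E", "F")

    ev: list[DemographicEvent] = []

    def split(t_kya: float, derived: Iterable[str], ancestral: str) -> None:
        for d in derived:
            ev.append(DemographicEvent("split", g(t_kya), d, ancestral))

    def pulse(t_kya: float, source: str, dest: str, prop: float) -> None:
        ev.append(DemographicEvent("pulse_introgression", g(t_kya), source, dest, prop))

    # Modern-human side splits (forward-time: derived splits from ancestral).
    split(q["tEAs_Eu"], ("EAs", "Eu"), ANC_EUR)
    split(q["tOOA"], ("WAf", ANC_EUR), ANC_OOA)
    split(q["tMbt"], ("Mbt", ANC_OOA), ANC_MBT)
    split(q["tAMH"], ("Kho", ANC_MBT), ANC_AMH)
    # Archaic side.
    split(q["tN_NI"], ("NI",), "N")
    split(q["tD_DI"], ("DI",), "D")
    split(q["tN_D"], ("N", "D"), ANC_ND)
    if has_xaf:
        split(q["tAMH_XAf"], (ANC_AMH, "XAf"), ANC_AMH_XAF)
        split(q["tAMH_Archaics"], (ANC_AMH_XAF, ANC_ND), ANC_HOMININ)
    else:
        split(q["tAMH_Archaics"], (ANC_AMH, ANC_ND), ANC_HOMININ)
    if has_xn:
        if model_id in ("C", "E"):
            split(q["tXn"], ("Xn",), "N")
        else:
            split(q["tXn"], ("Xn",), ANC_ND)
    split(q["tXe"], (ANC_HOMININ, "Xe"), ANC_ROOT)

    # Introgression pulses (forward-time source -> dest).
    pulse(q["tIntrogressionDI_Han"], "DI", "EAs", q["IntrogressionDI_Han"])
    pulse(q["tIntrogressionNI_Eurasia"], "NI", ANC_EUR, q["IntrogressionNI_Eurasia"])
    # Early modern humans into Neanderthals: the source is whichever
    # modern-human stem population is active at the pulse time.
    t_eh = q["tIntrogressionEarlyHumans_Neanderthal"]
    eh_source = ANC_AMH
    if has_xaf and t_eh > q["tAMH_XAf"]:
        eh_source = ANC_AMH_XAF
    pulse(t_eh, eh_source, "N", q["IntrogressionEarlyHumans_Neanderthal"])
    pulse(q["tIntrogressionXe_Denisovan"], "Xe", "D", q["IntrogressionXe_Denisovan"])
    if has_xaf:
        pulse(q["tIntrogressionXf_WestAfrica"], "XAf", "WAf", q["IntrogressionXf_WestAfrica"])
        pulse(q["tIntrogressionXf_Mbuti"], "XAf", "Mbt", q["IntrogressionXf_Mbuti"])
        pulse(q["tIntrogressionXf_Kho"], "XAf", "Kho", q["IntrogressionXf_Kho"])
    if has_xn:
        pulse(q["tIntrogressionXn_WestAfrica"], "Xn", "WAf", q["IntrogressionXn_WestAfrica"])
        pulse(q["tIntrogressionXn_Mbuti"], "Xn", "Mbt", q["IntrogressionXn_Mbuti"])
        pulse(q["tIntrogressionXn_Kho"], "Xn", "Kho", q["IntrogressionXn_Kho"])

    # Recent continuous migrations, active from tMigrationOnset to now.
    for donor, recipient in MIGRATION_PAIRS:
        ev.append(
            DemographicEvent(
                "continuous_migration",
                g(q["tMigrationOnset"]),
                donor,
                recipient,
                q[f"m{donor}_{recipient}"],
            )
        )

    ev.sort(key=lambda e: (e.time, e.kind, e.source, e.dest))
    return DemographicModel(
        model_id=model_id,
        populations=populations,
        events=ev,
        generation_time=generation_time,
        sample_ages={"N": g(sample_age_N), "D": g(sample_age_D)},
        params=dict(q),
    )
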