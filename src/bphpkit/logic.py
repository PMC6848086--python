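"""Boolean repression-logic model of the cyst/rod division decision.

Hypothesis encoded: in darkness the two bacteriophytochromes autophosphorylate
and, together with the hybrid histidine kinase, transfer phosphate to the
response-regulator pool, repressing rod-rod division (the colony then grows
by cyst-cyst division).  Red or far-red light photoactivates the
chromophore-bearing phytochromes, suppressing phosphorylation and lifting
the repression, so rod-rod divisions dominate.  Without the chromophore
(heme-oxygenase knockout) the phytochromes are light-blind and stay
phosphorylated; without either phytochrome, or without the kinase, the
repression cannot form at all.  Blue-containing light inhibits growth
outright through a separate (unmodeled) blue-light pathway.

Two mechanistic variants of the phytochrome cooperation are carried — a
BphP1/BphP2 heterodimer versus phosphotransfer converging on a shared
response regulator — which yield identical predictions for every strain and
light condition the observations cover; the variant is provenance on the
prediction, not a branch in the truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

__all__ = [
    "Light",
    "DivisionMode",
    "ModelVariant",
    "GenotypeCondition",
    "PhenotypeCall",
    "ScoreResult",
    "predict_phenotype",
    "score_model",
    "strain_genotype",
    "STRAIN_NAMES",
]


class Light(Enum):
    DARK = "dark"
    RED_660 = "red_660"
    FAR_RED_780 = "far_red_780"
    BLUE = "blue"
    WHITE = "white"


#: Light regimes that photoactivate bacteriophytochromes (white light
#: contains red wavelengths).
_PHYTOCHROME_ACTIVE_LIGHT = frozenset({Light.RED_660, Light.FAR_RED_780, Light.WHITE})
#: Light regimes containing growth-inhibiting blue wavelengths.
_BLUE_CONTAINING_LIGHT = frozenset({Light.BLUE, Light.WHITE})


class DivisionMode(Enum):
    CYST_CYST = "cyst_cyst"
    ROD_ROD = "rod_rod"
    NONE = "none"


class ModelVariant(Enum):
    HETERODIMER = "heterodimer"
    SHARED_RR = "shared_rr"


@dataclass(frozen=True)
class GenotypeCondition:
    """A strain genotype plus its growth condition."""

    bphp1_present: bool = True
    bphp2_present: bool = True
    hmuo_present: bool = True
    bhk_present: bool = True
    brr_present: bool = True
    light: Light = Light.DARK
    water_available: bool = True

    def __post_init__(self) -> None:
        if not isinstance(self.light, Light):
            raise TypeError("light must be a Light enum member")


@dataclass(frozen=True)
class PhenotypeCall:
    """Predicted phenotype; intermediates exposed for testing."""

    division_mode: DivisionMode
    growth_inhibited: bool
    repression_active: bool
    variant: ModelVariant
    note: str = ""


def predict_phenotype(
    gc: GenotypeCondition,
    variant: ModelVariant = ModelVariant.HETERODIMER,
    strict_brr: bool = False,
) -> PhenotypeCall:
    """Predict the division phenotype for a genotype x light condition.

    Total on all inputs.  ``strict_brr`` additionally gates repression on
    the response regulator; the default leaves it ungated because no
    observation constrains it (the regulator knockout could not be made).
    """
    chromophore_available = gc.hmuo_present
    photo_active = chromophore_available and gc.light in _PHYTOCHROME_ACTIVE_LIGHT
    # An absent protein contributes no phosphotransfer; a photoactivated
    # phytochrome is dephosphorylated.
    kinase_phosphorylated = not photo_active
    repression_active = (
        gc.bphp1_present
        and gc.bphp2_present
        and gc.bhk_present
        and kinase_phosphorylated
    )
    if strict_brr:
        repression_active = repression_active and gc.brr_present
    growth_inhibited = gc.light in _BLUE_CONTAINING_LIGHT
    note = ""
    if not gc.water_available:
        division = DivisionMode.NONE
        note = "no water: no division"
    elif growth_inhibited:
        division = DivisionMode.NONE
    elif repression_active:
        division = DivisionMode.CYST_CYST
        if gc.light is Light.DARK:
            note = "minor dark pathway: rare cyst-rod-cyst differentiation cycle"
    else:
        division = DivisionMode.ROD_ROD
    return PhenotypeCall(
        division_mode=division,
        growth_inhibited=growth_inhibited,
        repression_active=repression_active,
        variant=variant,
        note=note,
    )


STRAIN_NAMES = ("WT", "dHmuO", "dBphP1", "dBphP2", "dBHK")

_LIGHT_ALIASES = {
    "dark": Light.DARK,
    "red": Light.RED_660,
    "red_660": Light.RED_660,
    "660": Light.RED_660,
    "far_red": Light.FAR_RED_780,
    "far_red_780": Light.FAR_RED_780,
    "780": Light.FAR_RED_780,
    "blue": Light.BLUE,
    "white": Light.WHITE,
}


def parse_light(name) -> Light:
    if isinstance(name, Light):
        return name
    key = str(name).strip().lower().replace("-", "_").replace(" ", "_")
    if key in _LIGHT_ALIASES:
        return _LIGHT_ALIASES[key]
    raise ValueError(f"unknown light condition {name!r}")


def strain_genotype(
    strain: str, light, water_available: bool = True
) -> GenotypeCondition:
    """Build the genotype for one of the named knockout strains.

    Accepted names: WT, dHmuO, dBphP1, dBphP2, dBHK (case-insensitive;
    'delta'/'d' prefixes interchangeable).
    """
    key = strain.strip().lower().replace("delta", "d").replace("Δ", "d")
    gene_map = {
        "wt": {},
        "dhmuo": {"hmuo_present": False},
        "dbphp1": {"bphp1_present": False},
        "dbphp2": {"bphp2_present": False},
        "dbhk": {"bhk_present": False},
    }
    if key not in gene_map:
        raise ValueError(f"unknown strain {strain!r}; expected one of {STRAIN_NAMES}")
    return GenotypeCondition(
        light=parse_light(light), water_available=water_available, **gene_map[key]
    )


@dataclass(frozen=True)
class ScoreResult:
    n_observations: int
    n_matching: int
    mismatches: tuple[tuple[GenotypeCondition, DivisionMode, DivisionMode], ...]

    @property
    def all_match(self) -> bool:
        return self.n_matching == self.n_observations


def score_model(
    variant: ModelVariant,
    observations: Iterable[tuple[GenotypeCondition, DivisionMode]],
    strict_brr: bool = False,
) -> ScoreResult:
    """Count agreements between predictions and observed division modes.

    ``observations`` is an iterable of (condition, observed mode) pairs;
    mismatches are returned as (condition, observed, predicted) triples.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("observations table is empty")
    mismatches = []
    n_match = 0
    for gc, observed in obs:
        predicted = predict_phenotype(gc, variant=variant, strict_brr=strict_brr)
        if predicted.division_mode is observed:
            n_match += 1
        else:
            mismatches.append((gc, observed, predicted.division_mode))
    return ScoreResult(
        n_observations=len(obs), n_matching=n_match, mismatches=tuple(mismatches)
    )
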