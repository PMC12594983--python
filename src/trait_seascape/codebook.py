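"""Trait codebooks: effect traits with modality scores, and response traits.

Effect traits carry per-modality integer scores expressing the expected
contribution of the modality to benthic ecological processes (sediment
mixing, burrow ventilation, biodeposition, deposit feeding); response
traits describe life-history attributes used to classify taxa into
life-history strategies and carry no scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = [
    "Trait",
    "TraitCodebook",
    "effect_codebook",
    "response_codebook",
    "full_codebook",
]


@dataclass(frozen=True)
class Trait:
    """One trait: an id, a class, ordered modalities, optional scores."""

    trait_id: str
    name: str
    trait_class: str  # "effect" | "response"
    modalities: tuple[str, ...]
    scores: dict[str, int] | None = None  # effect traits only
    unit: str = ""

    def __post_init__(self) -> None:
        if self.trait_class not in ("effect", "response"):
            raise ValueError(f"unknown trait_class {self.trait_class!r}")
        if len(self.modalities) < 2:
            raise ValueError(f"trait {self.trait_id}: needs >=2 modalities")
        if self.scores is not None:
            missing = set(self.modalities) - set(self.scores)
            if missing:
                raise ValueError(f"trait {self.trait_id}: unscored modalities {sorted(missing)}")
            if any(s < 0 for s in self.scores.values()):
                raise ValueError(f"trait {self.trait_id}: negative modality score")

    def score(self, modality: str) -> int:
        if self.scores is None:
            raise ValueError(f"trait {self.trait_id} has no modality scores (response trait)")
        return self.scores[modality]


@dataclass
class TraitCodebook:
    """An ordered collection of traits, addressable by id."""

    traits: dict[str, Trait] = field(default_factory=dict)

    def __getitem__(self, trait_id: str) -> Trait:
        return self.traits[trait_id]

    def __contains__(self, trait_id: str) -> bool:
        return trait_id in self.traits

    def __iter__(self):
        return iter(self.traits.values())

    @property
    def trait_ids(self) -> list[str]:
        return list(self.traits)

    def add(self, trait: Trait) -> None:
        if trait.trait_id in self.traits:
            raise ValueError(f"duplicate trait id {trait.trait_id}")
        self.traits[trait.trait_id] = trait

    def subset(self, trait_ids) -> "TraitCodebook":
        return TraitCodebook({t: self.traits[t] for t in trait_ids})

    def validate_modality(self, trait_id: str, modality: str) -> None:
        if trait_id not in self.traits:
            raise KeyError(f"unknown trait {trait_id!r}")
        if modality not in self.traits[trait_id].modalities:
            raise KeyError(f"unknown modality {modality!r} for trait {trait_id!r}")

    def apply_overrides(self, path) -> "TraitCodebook":
        """Return a copy with score overrides from a YAML file.

        Expected layout: ``{trait_id: {modality: score, ...}, ...}``.
        """
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        out = TraitCodebook()
        for trait in self:
            if trait.trait_id in overrides:
                scores = dict(trait.scores or {})
                for mod, sc in overrides[trait.trait_id].items():
                    if mod not in trait.modalities:
                        raise KeyError(
                            f"override names unknown modality {mod!r} of {trait.trait_id}"
                        )
                    scores[mod] = int(sc)
                trait = Trait(
                    trait.trait_id, trait.name, trait.trait_class,
                    trait.modalities, scores, trait.unit,
                )
            out.add(trait)
        return out


# ---------------------------------------------------------------------------
# Bundled codebooks.
#
# Effect traits: eight traits whose modality scores grade the expected
# contribution to sediment reworking, burrow ventilation and feeding-mediated
# particle transfer. Scores increase with expected process intensity; a zero
# score (immobile taxa, no sediment mixing, no bioconstruction) annihilates
# the multiplicative indicators built on top of them.
# ---------------------------------------------------------------------------

_EFFECT = [
    Trait("BM", "Body mass", "effect",
          ("< 0.001", "0.001-0.010", "0.010-0.100", "0.100-1.000", "1.000-10.000", "> 10.000"),
          {"< 0.001": 1, "0.001-0.010": 2, "0.010-0.100": 3,
           "0.100-1.000": 4, "1.000-10.000": 5, "> 10.000": 6},
          unit="g AFDM"),
    Trait("FT", "Feeding type", "effect",
          ("De", "Su", "HeGr", "CaSc"),
          {"De": 1, "Su": 1, "HeGr": 1, "CaSc": 1}),
    Trait("SD", "Substratum depth occupancy", "effect",
          ("0", "0-5", "5-15", "15-30", "> 30"),
          {"0": 1, "0-5": 2, "5-15": 3, "15-30": 4, "> 30": 5},
          unit="cm"),
    Trait("MB", "Mobility", "effect",
          ("Immobile", "Limited", "Slow", "Fast", "Very fast"),
          {"Immobile": 0, "Limited": 1, "Slow": 2, "Fast": 3, "Very fast": 4}),
    Trait("AF", "Sediment mixing type", "effect",
          ("None", "Diffusion", "Upward conveying", "Downward conveying", "Regeneration"),
          {"None": 0, "Diffusion": 1, "Upward conveying": 1,
           "Downward conveying": 1, "Regeneration": 1}),
    Trait("VP", "Ventilation/Pumping", "effect",
          ("Null", "Low", "High"),
          {"Null": 1, "Low": 2, "High": 3}),
    Trait("BT", "Endo-bioconstruction type", "effect",
          ("None", "Blind-ended", "Open-ended"),
          {"None": 1, "Blind-ended": 2, "Open-ended": 3}),
    Trait("maxBD", "Endo-bioconstruction depth", "effect",
          ("None/Surficial", "0-5", "5-15", "15-30", "> 30"),
          {"None/Surficial": 0, "0-5": 1, "5-15": 2, "15-30": 3, "> 30": 4},
          unit="cm"),
]

# Response traits: life-history attributes (pace of life, reproductive
# investment, offspring survival) plus shared morphology/behaviour traits.
_RESPONSE = [
    Trait("LS", "Life span", "response",
          ("< 1", "1-3", "3-10", "10-20", "> 20"), unit="years"),
    Trait("AM", "Age at maturity", "response", ("< 1", "1-3", "> 3"), unit="years"),
    Trait("SX", "Sexuality", "response", ("Gonochorism", "Homogamy", "Protandry")),
    Trait("RF", "Reproductive frequency", "response",
          ("Sexual seasonal", "Sexual continuous", "Asexual")),
    Trait("FE", "Fertilization", "response", ("Broadcasting", "Spermcasting", "Pairing")),
    Trait("FEC", "Annual fecundity", "response",
          ("< 1e2", "1e2-1e3", "1e3-1e4", "1e4-1e5", "1e5-1e6", "> 1e6"),
          unit="offspring"),
    Trait("OT", "Offspring type", "response", ("Egg", "Larva", "Juvenile")),
    Trait("OS", "Offspring size", "response",
          ("< 0.1", "0.1-0.5", "0.5-1.5", "> 1.5"), unit="mm"),
    Trait("OP", "Offspring protection", "response",
          ("None", "Gel", "Capsule", "Bearing/Brooding")),
    Trait("OD", "Offspring development", "response",
          ("Planktotrophic", "Lecithotrophic", "Mixed planktotrophic",
           "Mixed lecithotrophic", "Internal")),
    Trait("OBD", "Offspring benthic stage duration", "response",
          ("Null", "< 15", "15-30", "30-60", "> 60"), unit="days"),
    Trait("OPD", "Offspring pelagic stage duration", "response",
          ("Null", "< 15", "15-30", "30-60", "> 60"), unit="days"),
    Trait("OSS", "Offspring settlement size", "response", ("< 0.5", "0.5-1.5", "> 1.5")),
    Trait("BMR", "Body mass", "response",
          ("< 0.001", "0.001-0.010", "0.010-0.100", "0.100-1.000", "> 1.000"),
          unit="g AFDM"),
    Trait("BL", "Body length", "response",
          ("< 1", "1-3", "3-10", "10-20", "> 20"), unit="cm"),
    Trait("MBR", "Mobility", "response",
          ("Immobile", "Limited", "Slow", "Fast", "Very fast")),
    Trait("SDR", "Substratum depth occupancy", "response",
          ("0", "0-5", "5-15", "15-30", "> 30"), unit="cm"),
    Trait("FTR", "Feeding type", "response", ("De", "Su", "HeGr", "CaSc")),
]


def effect_codebook() -> TraitCodebook:
    """The bundled effect-trait codebook (scored modalities)."""
    cb = TraitCodebook()
    for t in _EFFECT:
        cb.add(t)
    return cb


def response_codebook() -> TraitCodebook:
    """The bundled response-trait codebook (unscored modalities)."""
    cb = TraitCodebook()
    for t in _RESPONSE:
        cb.add(t)
    return cb


def full_codebook() -> TraitCodebook:
    cb = effect_codebook()
    for t in _RESPONSE:
        cb.add(t)
    return cb
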