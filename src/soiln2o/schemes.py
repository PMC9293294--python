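"""Emission-factor schemes: triangular EF parameters per inventory stratum.

A stratum is a (climate class, fertilizer component) pair.  Two presets ship
with the package:

``GL2006``
    The 2006 IPCC Guidelines single default, EF1 = 1% of applied N with a
    95% CI of 0.3%-3%, applied to every stratum.
``MR2019``
    The 2019 IPCC Methods Refinement disaggregation: dry climate 0.5%
    (0.0%-1.1%) for any fertilizer form, wet climate 1.6% (1.3%-1.9%) for
    synthetic and mixed forms, wet climate 0.6% (0.1%-1.1%) for organic
    (manure) forms.

Triangular parameterization: lower/upper are the 95% CI bounds, mode is the
reported mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .triangular import TriangularEF

__all__ = [
    "CLIMATES",
    "COMPONENTS",
    "EFScheme",
    "MissingStratumError",
    "gl2006",
    "mr2019",
    "load_scheme",
]

CLIMATES = ("wet", "dry")
COMPONENTS = ("synthetic", "manure")

Stratum = tuple[str, str]  # (climate, component)


class MissingStratumError(KeyError):
    """An EF scheme does not cover a (climate, component) stratum."""


@dataclass(frozen=True)
class EFScheme:
    """A named mapping from inventory strata to triangular EF distributions."""

    name: str
    strata: Mapping[Stratum, TriangularEF] = field(repr=False)

    def ef_for(self, climate: str, component: str) -> TriangularEF:
        try:
            return self.strata[(climate, component)]
        except KeyError:
            raise MissingStratumError(
                f"scheme {self.name!r} has no EF for climate={climate!r}, "
                f"component={component!r}"
            ) from None

    def mode_map(self) -> dict[Stratum, float]:
        """Point-estimate EF per stratum (the triangular mode)."""
        return {k: d.mode for k, d in self.strata.items()}

    def covers(self, strata) -> bool:
        return all(s in self.strata for s in strata)

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "name": self.name,
            "strata": [
                {
                    "climate": c,
                    "component": comp,
                    "lower": float(d.lower),
                    "mode": float(d.mode),
                    "upper": float(d.upper),
                }
                for (c, comp), d in sorted(self.strata.items())
            ],
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path, allow_negative: bool = False) -> "EFScheme":
        payload = yaml.safe_load(Path(path).read_text())
        strata = {
            (s["climate"], s["component"]): TriangularEF(
                float(s["lower"]),
                float(s["mode"]),
                float(s["upper"]),
                allow_negative=allow_negative,
            )
            for s in payload["strata"]
        }
        return cls(name=str(payload.get("name", Path(path).stem)), strata=strata)


def gl2006() -> EFScheme:
    """The 2006 IPCC Guidelines default EF1 (1%, 95% CI 0.3-3%), all strata."""
    tri = TriangularEF(0.003, 0.010, 0.030)
    return EFScheme(
        "GL2006",
        {(c, comp): tri for c in CLIMATES for comp in COMPONENTS},
    )


def mr2019() -> EFScheme:
    """The 2019 IPCC Methods Refinement EF1, disaggregated by climate/form."""
    dry = TriangularEF(0.000, 0.005, 0.011)
    wet_syn = TriangularEF(0.013, 0.016, 0.019)
    wet_man = TriangularEF(0.001, 0.006, 0.011)
    return EFScheme(
        "MR2019",
        {
            ("dry", "synthetic"): dry,
            ("dry", "manure"): dry,
            ("wet", "synthetic"): wet_syn,
            ("wet", "manure"): wet_man,
        },
    )


_PRESETS = {"gl2006": gl2006, "mr2019": mr2019}


def load_scheme(name_or_path: str) -> EFScheme:
    """Resolve a preset name (``gl2006``/``mr2019``) or a YAML file path."""
    key = str(name_or_path).lower()
    if key in _PRESETS:
        return _PRESETS[key]()
    path = Path(name_or_path)
    if path.exists():
        return EFScheme.from_yaml(path)
    raise ValueError(
        f"unknown EF scheme {name_or_path!r}; presets: {sorted(_PRESETS)}"
    )
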