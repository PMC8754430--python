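"""Genotype presets: fitted titration parameters for WT and subunit-a mutants.

Each preset carries the TD-occurrence curve (tmin percent, K1, K2 in pK
units) and the synthase-step model (pKa1, P1, pKa2, P2, percents) for one
genotype, so mutant-vs-WT comparisons can be simulated out of the box.
The leucine substitutions probe residues lining the two proton
half-channels of stator subunit-a (aN214, aQ252, aE219 input side; aE196
output side; aH245 near the channel).
"""

from __future__ import annotations

from .models import PHCurveModel, SynthaseStepModel

__all__ = ["GENOTYPES", "get_preset", "Preset"]


class Preset:
    """Bundle of the fitted pH models for one genotype.

    ``td_pkas`` are the apparent pKa values of TD formation as tabulated
    from the occurrence-curve fits (1 decimal); the tangent construction in
    `models.extract_pkas` reproduces them to ~0.1 pH units from K1/K2.
    """

    def __init__(
        self,
        name: str,
        td_model: PHCurveModel,
        synthase_model: SynthaseStepModel,
        td_pkas: tuple[float, float],
    ):
        self.name = name
        self.td_model = td_model
        self.synthase_model = synthase_model
        self.td_pkas = td_pkas

    def __repr__(self) -> str:  # pragma: no cover
        return f"Preset({self.name!r})"


GENOTYPES: dict[str, Preset] = {
    name: Preset(name, PHCurveModel(tmin=tmin, k1=k1, k2=k2),
                 SynthaseStepModel(pka1=pka1, p1=p1, pka2=pka2, p2=p2),
                 td_pkas=(tpk1, tpk2))
    for name, (k1, k2, tmin, tpk1, tpk2, pka1, p1, pka2, p2) in {
        "WT":     (6.4, 6.75, 22.0, 5.6, 7.5, 6.5, 38.0, 7.7, 33.0),
        "aN214L": (7.0, 7.50, 19.1, 6.3, 8.2, 8.0, 37.0, 8.4, 5.0),
        "aQ252L": (7.0, 7.40, 19.5, 6.3, 8.1, 5.9, 42.0, 6.4, 28.0),
        "aE219L": (6.9, 7.35, 17.8, 6.2, 8.0, 7.1, 32.0, 7.4, 35.0),
        "aH245L": (6.5, 6.87, 20.0, 5.6, 7.7, 7.3, 33.0, 7.7, 22.0),
        "aE196L": (6.3, 6.70, 20.0, 5.6, 7.4, 6.2, 34.0, 6.5, 28.0),
    }.items()
}


def get_preset(name: str) -> Preset:
    try:
        return GENOTYPES[name]
    except KeyError:
        raise KeyError(
            f"unknown genotype {name!r}; available: {sorted(GENOTYPES)}"
        ) from None
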