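"""Named ground-truth parameter bundles for the synthetic generator.

Each :class:`VariantPreset` encodes one experimental condition of the KIF22
variant study in CHON-001 chondrocytes as the set of per-condition means the
generator reproduces: the plateau of anaphase chromosome-mass separation, the
plateau of spindle-pole separation, the chromosome-ring radius on monopolar
spindles (the polar-ejection-force readout), the fraction of lobed interphase
nuclei, and the KIF22-channel expression level relative to the GFP-only
control line.

Condition naming: ``gfp_ctrl``/``gfp_kd`` are the GFP-only line with control
or KIF22 siRNA (endogenous KIF22 present or depleted); ``wt``, ``p144t``,
``e222q`` and ``r149q`` are lines over-expressing the respective KIF22-GFP
construct on top of endogenous KIF22; ``r49q_ctrl``/``r49q_kd`` are the
KIF22-R49Q line with control or KIF22 siRNA (the knockdown condition models
the homozygous patient state).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class VariantPreset:
    """Ground-truth condition means encoded by the generator.

    Attributes
    ----------
    name
        Condition label.
    max_chrom_sep_um
        Plateau of the anaphase chromosome-mass separation (um).
    max_pole_sep_um
        Plateau of the spindle-pole separation (um).
    initial_pole_sep_um
        Metaphase spindle length at anaphase onset (um).
    pef_radius_um
        Chromosome-ring radius on monopolar spindles (um); the proxy for
        relative polar ejection force.
    abnormal_frac
        Fraction of interphase nuclei drawn from the lobed component.
    expression_fold
        KIF22-channel intensity scale relative to the GFP-only control line.
    """

    name: str
    max_chrom_sep_um: float
    max_pole_sep_um: float
    initial_pole_sep_um: float
    pef_radius_um: float
    abnormal_frac: float
    expression_fold: float

    def __post_init__(self) -> None:
        if not 0 < self.max_chrom_sep_um < self.max_pole_sep_um:
            raise ValueError(
                "require 0 < max_chrom_sep_um < max_pole_sep_um "
                f"(got {self.max_chrom_sep_um}, {self.max_pole_sep_um})"
            )
        if not 0 <= self.abnormal_frac <= 1:
            raise ValueError("abnormal_frac must lie in [0, 1]")
        if not self.pef_radius_um > 0:
            raise ValueError("pef_radius_um must be positive")
        if not self.expression_fold > 0:
            raise ValueError("expression_fold must be positive")


def _p(name, chrom, pole, pef, abn, fold) -> VariantPreset:
    return VariantPreset(
        name=name,
        max_chrom_sep_um=chrom,
        max_pole_sep_um=pole,
        initial_pole_sep_um=9.0,
        pef_radius_um=pef,
        abnormal_frac=abn,
        expression_fold=fold,
    )


#: Packaged condition presets.  Separation plateaus and ring radii are the
#: study's per-condition means; ``abnormal_frac`` the reported percentage of
#: abnormally shaped nuclei; ``expression_fold`` the relative KIF22 level
#: (0.25 for the 75%-efficient knockdown, ~2x for the induced constructs).
#: The abnormal-nucleus fraction was not reported for the R149Q line; it is
#: set equal to E222Q, the variant of comparable segregation severity.
PRESETS: dict[str, VariantPreset] = {
    p.name: p
    for p in [
        _p("gfp_ctrl", 14.3, 22.0, 3.0, 0.044, 1.0),
        _p("gfp_kd", 17.2, 21.0, 1.2, 0.142, 0.25),
        _p("wt", 14.8, 21.3, 3.1, 0.196, 2.0),
        _p("p144t", 8.6, 17.4, 2.8, 0.679, 2.0),
        _p("e222q", 5.0, 14.4, 3.1, 0.467, 2.0),
        _p("r149q", 4.7, 15.8, 3.0, 0.467, 2.0),
        _p("r49q_ctrl", 11.4, 18.2, 3.0, 0.419, 2.0),
        _p("r49q_kd", 8.9, 18.9, 2.6, 0.612, 2.0),
    ]
}

#: Reported per-condition standard errors of the mean (um) for the three
#: distance readouts, keyed as (condition, readout).  Used by tests and the
#: acceptance machinery as the natural comparison scale for recovered means.
CONDITION_SEM_UM: dict[tuple[str, str], float] = {
    # chromosome-mass separation plateau
    ("gfp_ctrl", "chrom"): 0.37,
    ("gfp_kd", "chrom"): 0.37,
    ("wt", "chrom"): 0.37,
    ("p144t", "chrom"): 0.73,
    ("e222q", "chrom"): 0.61,
    ("r149q", "chrom"): 0.73,
    ("r49q_ctrl", "chrom"): 0.42,
    ("r49q_kd", "chrom"): 0.40,
    # spindle-pole separation plateau
    ("gfp_ctrl", "pole"): 0.37,
    ("gfp_kd", "pole"): 0.27,
    ("wt", "pole"): 0.51,
    ("p144t", "pole"): 0.05,
    ("e222q", "pole"): 0.40,
    ("r149q", "pole"): 0.56,
    ("r49q_ctrl", "pole"): 0.46,
    ("r49q_kd", "pole"): 0.38,
    # monopolar chromosome-ring radius (PEF readout)
    ("gfp_ctrl", "pef"): 0.05,
    ("gfp_kd", "pef"): 0.10,
    ("wt", "pef"): 0.05,
    ("p144t", "pef"): 0.80,
    ("e222q", "pef"): 0.04,
    ("r149q", "pef"): 0.05,
    ("r49q_ctrl", "pef"): 0.05,
    ("r49q_kd", "pef"): 0.06,
}


def get_preset(name: str) -> VariantPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset '{name}'; available: {sorted(PRESETS)}"
        ) from None
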