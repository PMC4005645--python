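"""Seeded generators for synthetic RNAs, ITC thermograms and NMR integral pairs.

Every generator is a pure function of its spec plus a seed, so fixtures are
reproduced bit-for-bit at test time instead of being shipped.  The RNA
generator plants one A(N)GGAX-family motif in a chosen structural context
(hairpin loop on a stem, expanded loop, single strand, or partially/fully
base-paired); the ITC generator adds Gaussian heat noise to the forward
isotherm (instrument-like); the NMR generator applies multiplicative
lognormal noise to ideal free/bound peak integrals (integration-like).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .motifs import ContextClass
from .rna import RnaMolecule
from .thermo import (
    BindingParameters,
    ItcExperiment,
    NmrIntegralPair,
    bound_fraction_forward,
    itc_isotherm,
)

__all__ = [
    "PlantedMotifSpec",
    "ItcDesign",
    "make_rna_with_motif",
    "make_itc",
    "make_integral_pairs",
    "sl2_reference_params",
    "sl2_itc_design",
    "PRESET_SPECS",
]

_COMPLEMENT = {"G": "C", "C": "G", "A": "U", "U": "A"}
_NONMOTIF = "ACU"  # loop/flank alphabet; two G's are needed to seed a spurious GGA


@dataclass(frozen=True)
class PlantedMotifSpec:
    """Recipe for one synthetic RNA with a single planted GGA context."""

    context: ContextClass
    n_base: str = "C"
    x_base: str = "U"
    stem_length: int = 4
    inserted_count: int = 2  # EXPANDED_LOOP only
    flank_lengths: tuple[int, int] = (4, 4)
    name: str = "synthetic"

    def __post_init__(self) -> None:
        loop_classes = (
            ContextClass.HEXALOOP_ON_STEM,
            ContextClass.PURINE_PENTALOOP,
            ContextClass.PENTALOOP_NO_N,
            ContextClass.EXPANDED_LOOP,
        )
        if self.context in loop_classes and self.stem_length < 2:
            raise ValueError(f"{self.context.value} requires stem_length >= 2")
        if self.context is ContextClass.PURINE_PENTALOOP and self.n_base not in "AG":
            raise ValueError("purine pentaloop requires N in {A, G}")
        if self.context is ContextClass.EXPANDED_LOOP and self.inserted_count < 1:
            raise ValueError("expanded loop requires >= 1 inserted nucleotide")


def _random_flank(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_NONMOTIF), size=length))


def _random_stem(rng: np.random.Generator, length: int, closing: Sequence[tuple[str, str]] = ()) -> tuple[str, str]:
    """5' and 3' strands of a complementary stem, 60% GC, loop-proximal last.

    ``closing`` fixes the top pairs (loop-proximal first), e.g. the C-G /
    U-A closing geometry of the measured hairpin constructs.
    """
    pairs: list[tuple[str, str]] = []
    for k in range(length):
        top_idx = length - 1 - k  # 0 = loop-proximal
        if top_idx < len(closing):
            pairs.append(closing[top_idx])
        else:
            b5 = rng.choice(["G", "C", "A", "U"], p=[0.3, 0.3, 0.2, 0.2])
            pairs.append((b5, _COMPLEMENT[b5]))
    five = "".join(p[0] for p in pairs)
    three = "".join(p[1] for p in reversed(pairs))
    return five, three


def _assemble_hairpin(
    rng: np.random.Generator,
    spec: PlantedMotifSpec,
    loop: str,
    gga_offset_in_loop: int,
) -> tuple[str, str, tuple[int, int]]:
    """seq, structure and planted GGA span for a hairpin-with-flanks layout."""
    closing = [("C", "G"), ("U", "A")]  # loop closed by C-G, then U-A below
    five, three = _random_stem(rng, spec.stem_length, closing=closing)
    f5 = _random_flank(rng, spec.flank_lengths[0])
    f3 = _random_flank(rng, spec.flank_lengths[1])
    seq = f5 + five + loop + three + f3
    struct = (
        "." * len(f5)
        + "(" * spec.stem_length
        + "." * len(loop)
        + ")" * spec.stem_length
        + "." * len(f3)
    )
    g1 = len(f5) + spec.stem_length + gga_offset_in_loop
    return seq, struct, (g1, g1 + 3)


def _build_once(rng: np.random.Generator, spec: PlantedMotifSpec) -> tuple[str, str, tuple[int, int]]:
    C = ContextClass
    if spec.context is C.HEXALOOP_ON_STEM:
        loop = "A" + spec.n_base + "GGA" + spec.x_base
        return _assemble_hairpin(rng, spec, loop, gga_offset_in_loop=2)
    if spec.context is C.PURINE_PENTALOOP:
        loop = "A" + spec.n_base + "GGA"
        return _assemble_hairpin(rng, spec, loop, gga_offset_in_loop=2)
    if spec.context is C.PENTALOOP_NO_N:
        loop = "AGGA" + spec.x_base
        return _assemble_hairpin(rng, spec, loop, gga_offset_in_loop=1)
    if spec.context is C.EXPANDED_LOOP:
        ins = _random_flank(rng, spec.inserted_count)
        loop = ins + "A" + spec.n_base + "GGA" + spec.x_base
        return _assemble_hairpin(rng, spec, loop, gga_offset_in_loop=spec.inserted_count + 2)
    if spec.context is C.SINGLE_STRANDED:
        f5 = _random_flank(rng, max(spec.flank_lengths[0], 1))
        f3 = _random_flank(rng, max(spec.flank_lengths[1], 1))
        core = "A" + "GGA" + spec.x_base  # AGGAX, N absent like the measured 9-mer
        seq = f5 + core + f3
        return seq, "." * len(seq), (len(f5) + 1, len(f5) + 4)
    if spec.context is C.PARTIALLY_PAIRED:
        # stem 5' strand ends ...GG at the loop; first loop base is A:
        # the GGA window has its two G's paired and the A unpaired.
        stem = max(spec.stem_length, 3)
        five, three = _random_stem(rng, stem - 2)
        five = five + "GG"
        three = "CC" + three
        loop = "A" + _random_flank(rng, 3)
        f5 = _random_flank(rng, spec.flank_lengths[0])
        f3 = _random_flank(rng, spec.flank_lengths[1])
        seq = f5 + five + loop + three + f3
        struct = (
            "." * len(f5) + "(" * stem + "." * len(loop) + ")" * stem + "." * len(f3)
        )
        g1 = len(f5) + stem - 2
        return seq, struct, (g1, g1 + 3)
    if spec.context is C.FULLY_PAIRED:
        # GGA buried mid-helix, UCC on the opposite strand
        stem = max(spec.stem_length, 5)
        upper = max((stem - 3) // 2, 1)
        lower = stem - 3 - upper
        top5, top3 = _random_stem(rng, upper)
        bot5, bot3 = _random_stem(rng, lower)
        five = bot5 + "GGA" + top5
        three = top3 + "UCC" + bot3
        loop = "A" + _random_flank(rng, 3)
        f5 = _random_flank(rng, spec.flank_lengths[0])
        f3 = _random_flank(rng, spec.flank_lengths[1])
        seq = f5 + five + loop + three + f3
        struct = (
            "." * len(f5) + "(" * stem + "." * len(loop) + ")" * stem + "." * len(f3)
        )
        g1 = len(f5) + lower
        return seq, struct, (g1, g1 + 3)
    raise ValueError(f"unsupported context {spec.context}")


def make_rna_with_motif(
    spec: PlantedMotifSpec, seed: int = 0
) -> tuple[RnaMolecule, tuple[int, int]]:
    """Synthesise one RNA with exactly one GGA, planted in ``spec.context``.

    Returns the molecule and the 0-based half-open span of the planted GGA.
    Random stems/flanks are resampled (bounded) until the planted window is
    the only GGA in the sequence, so scans see a single unambiguous motif.
    """
    rng = np.random.default_rng(seed)
    for _ in range(200):
        seq, struct, span = _build_once(rng, spec)
        hits = [i for i in range(len(seq) - 2) if seq[i : i + 3] == "GGA"]
        if hits == [span[0]]:
            mol = RnaMolecule.from_strings(
                f"{spec.name}_{spec.context.value}", seq, struct
            )
            return mol, span
    raise RuntimeError("could not build a clean construct in 200 attempts")


@dataclass(frozen=True)
class ItcDesign:
    """Injection schedule and noise level of a simulated titration."""

    n_injections: int = 35
    injection_volume: float = 8e-6  # L, within the instrument's 4-10 ul range
    cell_conc: float = 10e-6  # M dimer in cell
    syringe_conc: float = 300e-6  # M RNA in syringe
    cell_volume: float = 1.4e-3  # L
    temperature: float = 298.0  # K
    noise_sd: Optional[float] = None  # J; None = 1% of full scale
    noise_frac_full_scale: float = 0.01

    def experiment(self) -> ItcExperiment:
        return ItcExperiment(
            cell_conc=self.cell_conc,
            syringe_conc=self.syringe_conc,
            injection_volumes=[self.injection_volume] * self.n_injections,
            cell_volume=self.cell_volume,
            temperature=self.temperature,
        )


def make_itc(
    params: BindingParameters, design: ItcDesign, seed: int = 0
) -> ItcExperiment:
    """Forward-model heats plus seeded Gaussian noise -> a measurable experiment."""
    exp = design.experiment()
    ideal = itc_isotherm(params, exp)
    sd = design.noise_sd
    if sd is None:
        sd = design.noise_frac_full_scale * float(np.max(np.abs(ideal)))
    rng = np.random.default_rng(seed)
    exp.heats = ideal + rng.normal(0.0, sd, size=len(ideal))
    return exp


def sl2_reference_params() -> BindingParameters:
    """Two-site parameters of the tightest measured hairpin (SL2-like).

    The macroscopic dissociation constants are the measured 16 nM / 185 nM
    pair; the binding enthalpies are typical exothermic protein-RNA values
    (the reference measurements report only K_d).
    """
    return BindingParameters(
        model="two_site", kd1=16e-9, kd2=185e-9, dh1=-60e3, dh2=-45e3
    )


def sl2_itc_design(**overrides) -> ItcDesign:
    """35 x 8 ul of 300 uM RNA into 1.4 ml of 10 uM dimer, 1% noise."""
    return ItcDesign(**overrides)


def make_integral_pairs(
    kd: float,
    p_tot: float,
    r_tot: float,
    n_pairs: int,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> list[NmrIntegralPair]:
    """Ideal free/bound integral pairs with multiplicative lognormal noise.

    The ideal pair is (1-f, f) with f from :func:`bound_fraction_forward`;
    each peak is multiplied by a lognormal factor with coefficient of
    variation ``noise_cv`` (noise_cv=0 reproduces the exact fractions).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    f = bound_fraction_forward(kd, p_tot, r_tot)
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    pairs = []
    for k in range(n_pairs):
        noise = rng.lognormal(0.0, sigma, size=2) if sigma > 0 else np.ones(2)
        pairs.append(
            NmrIntegralPair(
                resonance_id=f"res{k + 1}",
                i_free=(1.0 - f) * noise[0],
                i_bound=f * noise[1],
            )
        )
    return pairs


# named fixture presets mirroring the measured constructs
PRESET_SPECS: dict[str, PlantedMotifSpec] = {
    "sl2_like": PlantedMotifSpec(
        ContextClass.HEXALOOP_ON_STEM, n_base="C", x_base="U", stem_length=4, name="sl2_like"
    ),
    "purine_pentaloop": PlantedMotifSpec(
        ContextClass.PURINE_PENTALOOP, n_base="G", stem_length=4, name="purine_pentaloop"
    ),
    "pentaloop_no_n": PlantedMotifSpec(
        ContextClass.PENTALOOP_NO_N, x_base="U", stem_length=4, name="pentaloop_no_n"
    ),
    "expanded_loop": PlantedMotifSpec(
        ContextClass.EXPANDED_LOOP, inserted_count=2, stem_length=4, name="expanded_loop"
    ),
    "ss9_like": PlantedMotifSpec(
        ContextClass.SINGLE_STRANDED, flank_lengths=(2, 2), name="ss9_like"
    ),
    "partially_buried_gga": PlantedMotifSpec(
        ContextClass.PARTIALLY_PAIRED, stem_length=5, name="partially_buried_gga"
    ),
    "buried_gga": PlantedMotifSpec(
        ContextClass.FULLY_PAIRED, stem_length=6, name="buried_gga"
    ),
}
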