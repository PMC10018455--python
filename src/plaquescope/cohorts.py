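"""The default synthetic study: two transgenic genotypes, planted lipid roles.

The default cohort mirrors the design of the tetramodal single-section
experiment it emulates: two APP transgenic genotypes -- ``tgArcSwe`` forming
compact plaques and ``tgSwe`` forming cored plaques with a diffuse periphery
-- three animals per genotype and 4-6 cortical plaques per animal at 10 um
pixel pitch.

The species panel plants every effect the analysis pipeline is meant to
recover:

* sulfatides depleted at plaques in both genotypes;
* three "continuous maturation" lipids (class III) whose whole-plaque
  enrichment is coupled to plaque maturity in both genotypes;
* three "core formation" lipids (class II) with a maturity-coupled core pool
  plus an independent, high-variance diffuse pool at the same m/z, so their
  A-beta correlation is present in the plaque center but genuinely absent at
  the whole-plaque level;
* five "plaque growth" lipids (class I) coupled at the whole-plaque level in
  both genotypes but, in the cored genotype, enriched only in the periphery
  -- hence uncorrelated in the plaque center there;
* five genotype-discriminative lipids with strongly different abundance
  between the genotypes (uncoupled to maturity);
* filler lipids maturity-coupled in exactly one genotype (abundance-matched
  between genotypes so they carry no genotype contrast), sized so that each
  of the four top-k correlation lists (whole/center x genotype) contains
  exactly k = 15 strongly coupled lipids;
* abundant background-only lipids that stabilise the total ion current;
* A-beta proteoforms in the peptide range: A-beta 1-40 (amplitude
  proportional to maturity; the correlation target), A-beta 1-42 (core
  kernel, amplitude proportional to maturity squared) and A-beta 1-38.

Strongly coupled species use maturity coupling beta = 3 with small
plaque-to-plaque jitter (sigma 0.05); matched uncoupled counterparts have
their effect size scaled by (1 + beta * E[maturity]) so genotype means agree.
These choices follow an a-priori signal-to-noise analysis of the pooled
Pearson design (about 15 plaques per genotype); see docs/methods.md.
"""

from __future__ import annotations

from .msi_io import ABETA_1_38, ABETA_1_40, ABETA_1_42, PROTON_MASS, compute_peptide_mass
from .synthetic import CohortConfig, GenotypeSpec, NoiseSpec, SpeciesSpec

COMPACT_GENOTYPE = "tgArcSwe"
CORED_GENOTYPE = "tgSwe"

#: coupling strength of maturity-coupled species
BETA = 3.0
#: mean maturity under the default Uniform(0.3, 1.0) draw
MEAN_MATURITY = 0.65
#: factor matching the mean enrichment of an uncoupled counterpart
MATCH = 1.0 + BETA * MEAN_MATURITY  # 2.95


def _coupled(name, mz, mode, base, pattern, effect, *, cls="none",
             lipid_class="", jitter=0.05):
    return SpeciesSpec(name=name, mz=mz, ion_mode=mode, base_abundance=base,
                       pattern=pattern, effect_size=effect,
                       maturity_coupling=BETA, plaque_jitter=jitter,
                       truth_class=cls, lipid_class=lipid_class)


def _uncoupled(name, mz, mode, base, pattern, effect, *, cls="none",
               lipid_class="", jitter=0.25, discriminative=False):
    return SpeciesSpec(name=name, mz=mz, ion_mode=mode, base_abundance=base,
                       pattern=pattern, effect_size=effect,
                       maturity_coupling=0.0, plaque_jitter=jitter,
                       truth_class=cls, lipid_class=lipid_class,
                       discriminative=discriminative)


def _matched(name, mz, mode, base, pattern, effect, **kw):
    """Uncoupled counterpart whose mean enrichment matches a coupled twin.

    Large independent per-plaque jitter keeps its residual footprint-geometry
    coupling from masquerading as a maturity correlation."""
    kw.setdefault("jitter", 0.5)
    return _uncoupled(name, mz, mode, base, pattern, effect * MATCH, **kw)


def _background(name, mz, mode, base, lipid_class=""):
    return SpeciesSpec(name=name, mz=mz, ion_mode=mode, base_abundance=base,
                       pattern="background_only", lipid_class=lipid_class)


def _diffuse_pool(name, mz, mode, base):
    """Independent high-variance peripheral pool co-binned with a core pool."""
    return SpeciesSpec(name=f"{name} diffuse pool", mz=mz, ion_mode=mode,
                       base_abundance=base, pattern="enriched_periphery",
                       effect_size=26.0, maturity_coupling=0.0,
                       plaque_jitter=0.6, annotate=False)


def abeta_mz(sequence: str) -> float:
    """[M+H]+ m/z of an A-beta proteoform at linear-TOF (average) mass."""
    return compute_peptide_mass(sequence, mode="average") + PROTON_MASS


def default_panels() -> tuple[list[SpeciesSpec], list[SpeciesSpec]]:
    """Species panels for (compact genotype, cored genotype)."""
    compact: list[SpeciesSpec] = []
    cored: list[SpeciesSpec] = []

    def both(spec: SpeciesSpec) -> None:
        compact.append(spec)
        cored.append(spec)

    # --- sulfatide depletion (both genotypes) ------------------------------
    both(_uncoupled("ST(24:1)", 888.62, "neg", 25.0, "depleted", 0.8,
                    lipid_class="ST", jitter=0.1))
    both(_uncoupled("ST(24:0)", 890.64, "neg", 20.0, "depleted", 0.7,
                    lipid_class="ST", jitter=0.1))

    # --- class III: continuous maturation (coupled everywhere) -------------
    for name, mz, mode, base, lc in [
        ("GM1(d36:1)", 1544.93, "neg", 12.0, "GM"),
        ("LPC(16:0)", 496.34, "pos", 18.0, "LPC"),
        ("LPC(18:1)", 522.36, "pos", 15.0, "LPC"),
    ]:
        both(_coupled(name, mz, mode, base, "enriched_whole", 2.0,
                      cls="III", lipid_class=lc))

    # --- class II: core formation (core pool + independent diffuse pool) ---
    for name, mz, mode, base, lc in [
        ("CerP(d36:1)", 644.50, "neg", 10.0, "CerP"),
        ("PE-Cer(d38:1)", 715.60, "neg", 12.0, "PE-Cer"),
        ("PS(40:9)", 828.50, "neg", 9.0, "PS"),
    ]:
        both(_coupled(name, mz, mode, base, "enriched_core", 5.0,
                      cls="II", lipid_class=lc))
        both(_diffuse_pool(name, mz, mode, base))

    # --- class I: plaque growth ------------------------------------------
    # whole-plaque coupled in the compact genotype; periphery-coupled (center-
    # silent) in the cored genotype.
    for name, mz, mode, base, lc in [
        ("LPI(18:0)", 599.32, "neg", 14.0, "LPI"),
        ("PI(38:4)", 885.55, "neg", 16.0, "PI"),
        ("LPE(O-16:1)", 452.28, "neg", 10.0, "LPE"),
        ("LPC(20:4)", 544.34, "pos", 12.0, "LPC"),
        ("LPC(22:6)", 568.34, "pos", 10.0, "LPC"),
    ]:
        compact.append(_coupled(name, mz, mode, base, "enriched_whole", 1.5,
                                cls="I", lipid_class=lc))
        cored.append(_coupled(name, mz, mode, base, "enriched_periphery", 3.2,
                              cls="I", lipid_class=lc))

    # --- designated genotype-discriminative lipids (uncoupled) -------------
    for name, mz, mode, base, lc, e_compact, e_cored in [
        ("PE(P-36:4)", 722.51, "neg", 14.0, "PE", 4.0, 0.5),
        ("PA(40:6)", 747.50, "neg", 11.0, "PA", 3.5, 0.4),
        ("PE(40:6)", 790.54, "neg", 13.0, "PE", 3.0, 0.3),
        ("PS(40:6)", 834.53, "neg", 12.0, "PS", 0.4, 3.0),
        ("SM(d36:1)", 769.62, "pos", 13.0, "SM", 0.3, 3.5),
    ]:
        compact.append(_uncoupled(name, mz, mode, base, "enriched_whole",
                                  e_compact, lipid_class=lc, discriminative=True))
        cored.append(_uncoupled(name, mz, mode, base, "enriched_whole",
                                e_cored, lipid_class=lc, discriminative=True))

    # --- fillers: coupled in exactly one genotype, abundance-matched --------
    # whole-kernel fillers
    whole_compact = [("PS(36:1)", 788.54, "neg", 10.0, "PS"),
                     ("GM3(d36:1)", 1179.73, "neg", 9.0, "GM")]
    whole_cored = [("PE(38:4)", 766.54, "neg", 12.0, "PE"),
                   ("PI(38:5)", 883.53, "neg", 10.0, "PI"),
                   ("GM1(d38:1)", 1572.93, "neg", 8.0, "GM"),
                   ("PS(36:2)", 786.53, "neg", 9.0, "PS")]
    for name, mz, mode, base, lc in whole_compact:
        compact.append(_coupled(name, mz, mode, base, "enriched_whole", 1.6,
                                lipid_class=lc))
        cored.append(_matched(name, mz, mode, base, "enriched_whole", 1.6,
                              lipid_class=lc))
    for name, mz, mode, base, lc in whole_cored:
        cored.append(_coupled(name, mz, mode, base, "enriched_whole", 1.6,
                              lipid_class=lc))
        compact.append(_matched(name, mz, mode, base, "enriched_whole", 1.6,
                                lipid_class=lc))

    # periphery-kernel fillers (whole-coupled, center-silent)
    peri_compact = [("LPE(17:2)", 462.26, "neg", 9.0, "LPE"),
                    ("LPC(18:0)", 562.37, "pos", 14.0, "LPC"),
                    ("PA(36:2)", 699.50, "neg", 10.0, "PA"),
                    ("PE(36:1)", 744.55, "neg", 12.0, "PE"),
                    ("PS(38:6)", 810.53, "neg", 10.0, "PS")]
    peri_cored = [("LPE(18:1)", 478.29, "neg", 11.0, "LPE"),
                  ("PS(O-32:1)", 720.52, "pos", 10.0, "PS"),
                  ("PE(O-34:1)", 702.54, "neg", 11.0, "PE")]
    for name, mz, mode, base, lc in peri_compact:
        compact.append(_coupled(name, mz, mode, base, "enriched_periphery", 3.0,
                                lipid_class=lc))
        cored.append(_matched(name, mz, mode, base, "enriched_periphery", 3.0,
                              lipid_class=lc))
    for name, mz, mode, base, lc in peri_cored:
        cored.append(_coupled(name, mz, mode, base, "enriched_periphery", 3.0,
                              lipid_class=lc))
        compact.append(_matched(name, mz, mode, base, "enriched_periphery", 3.0,
                                lipid_class=lc))

    # core-pool fillers (center-coupled, whole-silent; with diffuse pools)
    core_compact = [("CerP(d34:1)", 616.47, "neg", 9.0, "CerP"),
                    ("GM2(d36:1)", 1382.83, "neg", 8.0, "GM")]
    core_cored = [("PE-Cer(d38:2)", 713.58, "neg", 10.0, "PE-Cer"),
                  ("CerP(d42:2)", 754.59, "neg", 9.0, "CerP"),
                  ("SM(d34:1)", 703.57, "pos", 11.0, "SM"),
                  ("PE-Cer(d36:1)", 687.54, "neg", 10.0, "PE-Cer"),
                  ("CerP(d40:1)", 728.59, "neg", 8.0, "CerP")]
    for name, mz, mode, base, lc in core_compact:
        compact.append(_coupled(name, mz, mode, base, "enriched_core", 5.0,
                                lipid_class=lc))
        cored.append(_matched(name, mz, mode, base, "enriched_core", 5.0,
                              lipid_class=lc))
        both(_diffuse_pool(name, mz, mode, base))
    for name, mz, mode, base, lc in core_cored:
        cored.append(_coupled(name, mz, mode, base, "enriched_core", 5.0,
                              lipid_class=lc))
        compact.append(_matched(name, mz, mode, base, "enriched_core", 5.0,
                                lipid_class=lc))
        both(_diffuse_pool(name, mz, mode, base))

    # --- abundant background lipids (TIC stabilisers) ----------------------
    for name, mz, mode, base, lc in [
        ("PE(36:2)", 742.54, "neg", 120.0, "PE"),
        ("PG(36:2)", 773.53, "neg", 110.0, "PG"),
        ("PI(34:0)", 837.55, "neg", 140.0, "PI"),
        ("PE(38:6)", 762.51, "neg", 165.0, "PE"),
        ("PG(34:1)", 719.50, "neg", 150.0, "PG"),
        ("PI(36:2)", 861.55, "neg", 180.0, "PI"),
        ("HexCer(24:0)", 824.66, "neg", 190.0, "HexCer"),
        ("PA(34:1)", 673.48, "neg", 140.0, "PA"),
        ("PC(32:0)", 734.57, "pos", 320.0, "PC"),
        ("PC(34:1)", 760.59, "pos", 300.0, "PC"),
        ("PC(36:1)", 788.62, "pos", 240.0, "PC"),
        ("PC(38:4)", 810.60, "pos", 220.0, "PC"),
        ("SM(d42:2)", 813.68, "pos", 180.0, "SM"),
    ]:
        both(_background(name, mz, mode, base, lc))

    # --- peptide modality ---------------------------------------------------
    # an abundant peptide-range background anchors the modality's total ion
    # current so the A-beta peaks do not self-normalize away their own
    # amplitude variation
    for mz, base in [(1620.0, 90.0), (1905.0, 80.0), (2120.0, 75.0),
                     (2452.0, 70.0), (2840.0, 60.0), (3204.0, 55.0),
                     (3615.0, 45.0), (5030.0, 30.0)]:
        both(_background(f"bg peptide {mz:.0f}", mz, "peptide", base))
    both(SpeciesSpec(name="Abeta1-38", mz=abeta_mz(ABETA_1_38), ion_mode="peptide",
                     base_abundance=1.0, pattern="enriched_whole", effect_size=10.0,
                     maturity_coupling=0.0, maturity_exponent=1.0,
                     plaque_jitter=0.1, lipid_class="Abeta"))
    both(SpeciesSpec(name="Abeta1-40", mz=abeta_mz(ABETA_1_40), ion_mode="peptide",
                     base_abundance=2.0, pattern="enriched_whole", effect_size=30.0,
                     maturity_coupling=0.0, maturity_exponent=1.0,
                     plaque_jitter=0.03, lipid_class="Abeta"))
    both(SpeciesSpec(name="Abeta1-42", mz=abeta_mz(ABETA_1_42), ion_mode="peptide",
                     base_abundance=1.5, pattern="enriched_core", effect_size=30.0,
                     maturity_coupling=0.0, maturity_exponent=2.0,
                     plaque_jitter=0.05, lipid_class="Abeta"))

    return compact, cored


def default_config(seed: int = 0, noise: NoiseSpec | None = None,
                   **overrides) -> CohortConfig:
    """The default two-genotype cohort configuration."""
    compact, cored = default_panels()
    genotypes = [GenotypeSpec(COMPACT_GENOTYPE, "compact", compact),
                 GenotypeSpec(CORED_GENOTYPE, "cored", cored)]
    kwargs = dict(genotypes=genotypes, seed=seed)
    if noise is not None:
        kwargs["noise"] = noise
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def noiseless_config(seed: int = 0, **overrides) -> CohortConfig:
    """Default design with instrument noise switched off (biological
    plaque-to-plaque jitter and tissue texture remain: they are part of the
    emulated biology, not of the instrument)."""
    return default_config(seed=seed, noise=NoiseSpec(0.0, 0.0, 0.0), **overrides)
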