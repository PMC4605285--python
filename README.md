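# silnas

Mapping and **absolute quantification of post-transcriptional RNA
modifications** from LC-MS data of nuclease digests, using a stable-isotope
labeled in-vitro transcript as an internal standard (the SILNAS strategy).

## Who this is for

Analysts working on rRNA/tRNA modification mapping by mass spectrometry:
the package covers the complete computational side of an isotope-dilution
RNase-mapping experiment — in-silico digestion, theoretical ion
calculation, feature matching, light/heavy pairing, stoichiometry
estimation, pseudouridine detection by cyanoethylation, and assembly of a
per-position modification map — plus a simulator that generates
ground-truthed synthetic LC-MS data so every stage is testable without
instrument files.

## The method in brief

A cellular RNA is mixed 1:1 with an unmodified in-vitro transcript of the
same sequence whose G (or C/U) residues are fully ¹³C-labeled
(G: +10 × 1.0033548 Da, C/U: +9 ×). After digestion with a base-specific
RNase (T1 cuts 3′ of G, A cuts 3′ of pyrimidines; 2′-O-methylated sites
resist cleavage) every unmodified fragment appears as a **co-eluting
light/heavy doublet of equal height**. A modification breaks the pattern —
by a mass shift (methyl +14.0157, acetyl +42.0106, …), by a retention
shift (mass-silent pseudouridine, Ψ), or by a missing cleavage
(2′-O-methyl). Because the heavy reference is unmodified and equimolar,
the fraction modified at a site is simply

```
f = 1 − I_light,unmodified / I_heavy
```

Ψ is discriminated from U by acrylonitrile cyanoethylation (+53.0265 Da
per adduct), which converts ~30% of Ψ but only ~5% of U under optimized
conditions; the adduct fraction of a fragment is tested against those two
hypotheses, with Benjamini–Hochberg control across fragments, and the
adduct position is read from the CID ladder (c/y/w/a−B series) of the
derivatized species. Base-vs-ribose methyl placement uses the diagnostic
loss of the methylated base from the precursor.

## Worked example

Theoretical ions of the T1 fragment AAUUGp (5′-OH, 3′-phosphate):

```console
$ silnas mass --seq AAUUG --three-prime p --charge 2
neutral_mass    1633.2136
mz_2-   815.60
```

adding `--label heavy-g` gives the ¹³C₁₀-guanosine reference at m/z
820.62 — the 10.03 Da doublet spacing (5.02 at 2−) by which every
fragment pair is recognized.

End-to-end on simulated data — a 30-mer with a partial Ψ (76%), a
cleavage-blocking Gm (92%) and a complete base methyl:

```python
from silnas import (AnnotatedSequence, SimConfig, simulate, simulate_ce,
                    run_pipeline, PipelineConfig)

parent = AnnotatedSequence("demo", "AAGCCUAGAAUUGCAGUCAGGCUAAGUACG",
                           mods={6: "Y", 13: "Gm", 24: "m6A"})
cfg = SimConfig(parents=[parent],
                fractions={("demo", 6): 0.76, ("demo", 13): 0.92,
                           ("demo", 24): 1.0},
                intensity_cv=0.0, mass_error_ppm_sd=0.0, rt_jitter_sd=0.0,
                include_msms=True, seed=1)
sim = simulate(cfg)
post_ce = simulate_ce(sim)                      # cyanoethylation run
plain = AnnotatedSequence("demo", parent.residues)   # no prior knowledge
result = run_pipeline([plain], sim.features, post_ce, PipelineConfig())
for site in result.ptm_map.sites:
    print(f"{site.parent_id}  {site.position:>3}  {site.mod_code:<4} f={site.f:.3f}")
```

prints the recovered map — position, modification type and stoichiometry
— exactly matching the simulated truth:

```
demo    6  Y    f=0.760
demo   13  Gm   f=0.920
demo   24  m6A  f=1.000
```

The same flow is available from the shell (`silnas simulate … --ce`,
`silnas run …`), and `silnas digest / index / match / quant / assemble`
expose the intermediate stages. Observed data enter as TSV feature tables
(m/z, charge, rt_sec, intensity, optional MS/MS peak lists) or by targeted
extracted-ion-chromatogram extraction from mzML.

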