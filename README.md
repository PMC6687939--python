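# sipsyn

Stable-isotope-probing (SIP) metagenomics of syntrophic communities, end to
end: the bioenergetics of anaerobic fatty-acid degradation, a synthetic
DNA-SIP experiment generator with known ground truth, heavy-fraction
selection from density-gradient qPCR profiles, a negative-binomial
¹³C-enrichment caller for genome bins and OTUs, and fragment-based ANI
population delineation.

## The problem

In anaerobic digesters, butyrate is degraded by an obligate partnership:
syntrophic acetogens oxidize it to acetate and H₂ — a reaction that is
endergonic under standard conditions (ΔG°′ = +53 kJ/mol) and only becomes
exergonic when methanogens keep the products scarce:

    butyrate⁻ + 2 H₂O → 2 acetate⁻ + 2 H₂ + H⁺
    ΔG = ΔG°′ + RT ln Q,  Q = a²(acetate) · a²(H₂) · a(H⁺)/10⁻⁷ / a(butyrate)

DNA-SIP identifies which community members actually do this: feeding
¹³C-labeled substrate makes the degraders' DNA denser (buoyant density
ρ = 1.660 + 0.098·GC + 0.036·(¹³C atom fraction above natural abundance)),
so it can be separated on a CsCl gradient, located by qPCR, and sequenced.
Comparing heavy-fraction read counts between ¹³C and ¹²C control microcosms
with a negative-binomial Wald test (the DESeq2-style computation is
implemented here from first principles) calls the ¹³C-assimilating
populations; average nucleotide identity then places those genomes among
known relatives (≥ 95 % ANI = same species, ≥ 99 % = same sequence-discrete
population).

This package is for microbial ecologists and engineers who want those
computations as tested, seedable library functions — plus a full synthetic
SIP experiment simulator to validate the inference chain against known
ground truth.

## Worked example

```python
from sipsyn import thermo
from sipsyn.thermo import BUTYRATE_OXIDATION, EnvironmentalConditions

cond = EnvironmentalConditions(
    temperature=298.15, pH=7.0,
    activities={"butyrate": 1e-3, "acetate": 1e-3, "H2": 1e-5},  # 1 mM, 1 mM, 1 Pa
)
print(thermo.delta_g(BUTYRATE_OXIDATION, 53.0, cond))          # -21.2 kJ/mol
print(thermo.threshold_activity(BUTYRATE_OXIDATION, 53.0, cond,
                                "acetate", -10.0) * 1e3)       # 9.58 mM
```

The first number says butyrate oxidation yields −21.2 kJ/mol under typical
bioreactor conditions — exergonic only because H₂ is at 1 Pa. The second
says acetate accumulating to ~10 mM pushes ΔG above the −10 kJ/mol
catabolic threshold, i.e. acetate scavenging by methanogens is essential.

The full synthetic pipeline runs from the shell:

```sh
sipsyn run --seed 3 --out run3/
```

which simulates a 50-population community with 2 labeled degraders,
separates the DNA on a 24-fraction gradient, selects heavy fractions,
draws duplicate ¹²C/¹³C count matrices at 5×10⁵ reads, and calls enrichment.
With seed 3 it reports exactly the two labeled populations:

```
2 feature(s) 13C-enriched at alpha=0.05 (BH p, LFC >= 0.0):
  pop_06  log2FC=8.13  p=7.53e-44  padj=1.88e-42
  pop_18  log2FC=8.02  p=3.57e-65  padj=1.79e-63
```

Other subcommands: `sipsyn simulate`, `sipsyn select`, `sipsyn enrich`,
`sipsyn ani`, and `sipsyn thermo dg|threshold|partition|bmp`. For example
`sipsyn thermo bmp` prints the COD-based theoretical methane potential of the
microcosm feeding (1.82 g COD/g butyric acid; 25.3 mL CH₄ from 40 mM in
10 mL at 35 °C).

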