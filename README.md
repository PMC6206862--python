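# lxthet

Line × Tester heterosis genetics on dominant SSR band data: combining
ability, five heterosis statistics, admixture population structure,
linkage disequilibrium, Q+K mixed-model association mapping, stable-QTL
consensus calling and favorable-allele mining — with a synthetic-data
generator that plants known QTL so every stage can be verified end to end.

## Who this is for

Breeders and quantitative geneticists analyzing an L×T mating design —
a large set of female inbred lines each crossed to a small set of elite
testers — phenotyped in replicated multi-environment trials (the built-in
trait vocabulary is the ten cotton yield/fiber traits PH, BW, LP, BN, FL,
FS, MIC, FU, FE, FUI) and genotyped with multi-band microsatellites scored
as dominant band presence/absence (1/0, with STRUCTURE-style `-9` or
TASSEL-style `?` missing tokens).

## The models

**Combining ability.** Each cross mean decomposes as
x̄*ij* = μ + g*i* + g*j* + s*ij*, with line GCA g*i*, tester GCA g*j* and
SCA s*ij* each summing to zero. The L×T ANOVA splits the crosses stratum
into lines, testers and line×tester; variance components follow
σ²_sca = (MS_L×T − MS_error)/r and the half-sib form for σ²_gca.

**Heterosis.** Per cross × trait: mid-parent heterosis
MP = 100·(F1 − MPV)/MPV with MPV = (P1+P2)/2; heterobeltiosis
HB = 100·(F1 − BP)/BP with BP the better parent in the trait's desired
direction (lower for micronaire); heterosis index HI = 100·F1/MPV; and
standard heterosis K3/K4 against two commercial check cultivars, with the
check mean matched by environment before averaging.

**Population structure.** A Gibbs sampler for the admixture model with
correlated allele frequencies, treating each band as a haploid 0/1 locus;
LnP(D) = mean(ln L) − ½·var(ln L) over the retained sweeps; K selected by
the Evanno ΔK second-difference statistic; individuals assigned to a
subpopulation when their membership Q exceeds 0.5.

**LD.** Haploid 2×2 linkage disequilibrium per band pair
(r² = D²/(p_A q_A p_B q_B), D′ = |D|/D_max), aggregated to locus level by
frequency-product weights; permutation significance (1000 shuffles);
rare bands (frequency < 0.05) masked to missing; background LD = 99th
percentile of unlinked-pair r²; decay distance from the least-squares fit
of r² on ln(distance) at the r² = 0.2 threshold.

**Association.** The unified mixed model y = Xβ + Zu + e with
u ~ N(0, σ²_g K) on a simple-matching kinship K and optional Q-matrix
covariates; variance components by REML via spectral decomposition, held
fixed across markers (P3D); every band tested by generalized least
squares over the design's 32 genotype/phenotype combinations (trait
phenotype, GCA, SCA and the five heterosis statistics, paired with the
maternal-line panel or each tester's F1 family).

**Post-scan.** Records at −log₁₀ p > 3 feed the stable-QTL rule (support
from F1 families of ≥ 3 of the 5 testers), effect typing (GCA ⇒ additive;
SCA or heterosis ⇒ dominance), A/D subgenome and pleiotropy summaries,
and allele-effect mining a*i* = (carrier mean) − (overall mean).

## Worked example

`examples/` holds one short script per capability. From
`examples/05_association_scan.py` (60 lines × 5 testers, an additive
fiber-length QTL planted on marker M001 and a pure-dominance boll-weight
QTL on M006):

```
scan records: 49600 over 32 combinations
significant (-log10 p > 3) by variable class:
GCA           5
SCA           2
heterosis    32
phenotype     8
additive FL QTL on M001: significant with variables ['GCA', 'K3', 'phenotype']
dominance BW QTL on M006: significant with variables ['HB', 'HI', 'K3', 'K4', 'MP', 'SCA', 'phenotype']
```

The additive QTL surfaces through GCA, the dominance QTL through SCA and
the heterosis statistics — the separation of gene action the L×T
association design exists to deliver. Continuing in
`examples/06_stable_qtls_alleles.py`, the boll-weight QTL passes the
≥3-tester stability rule and is typed `dominance`:

```
47 significant records -> 2 stable QTLs
  BW @ M006: 3 testers, effect type dominance
```

A thin CLI covers shell use: `lxthet simulate`, `lxthet convert`
(band-matrix dialects), `lxthet run --config cfg.yaml`, `lxthet report`.

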