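# lymphofoci

Quantitative scoring of **53BP1 nuclear-focus patterns** in
immunofluorescence images of gastrointestinal lymphoid lesions, with
dual-color interphase **FISH genotyping** of MALT lymphoma and the
diagnostic statistics that turn both into a biopsy-level test.

53BP1 accumulates into discrete nuclear foci (NF) at DNA double-strand
breaks, so its immunofluorescent pattern reads out DNA-damage-response
activity and, indirectly, genomic instability. Each nucleus is assigned one
of five expression types:

| type | definition | grouped as |
|---|---|---|
| stable | no or weak staining, no discrete foci | normal |
| low DDR | 1–2 discrete NF, all < 1 µm | normal |
| high DDR | ≥ 3 discrete NF, all < 1 µm | **abnormal** |
| large focus | any NF ≥ 1 µm | **abnormal** |
| diffuse | intense, heterogeneous pan-nuclear staining | **abnormal** |

The per-case **abnormal fraction** — the percentage of nuclei in the three
abnormal classes — separates malignant lymphomas (follicular lymphoma,
mantle cell lymphoma) from benign lymphoid lesions (germinal centers,
primary follicles, mantle–marginal zones, simple lymphoid accumulations).
Operating cutoffs come from ROC analysis with Youden's index
J = sensitivity + specificity − 1; group contrasts use the exact
(permutation) Wilcoxon rank-sum test with mid-ranks for ties. For MALT
lymphoma, dual-color FISH (green 11q22/BIRC3, orange 18q21/MALT1) calls
t(11;18)(q21;q21) from colocalized green–orange fusion signals and trisomy
18q21 from a 3-orange/2-green pattern; a high abnormal fraction marks the
translocation-positive, eradication-resistant "high-risk" cases.

Because the original biopsy images are not public, the package ships a
first-class synthetic generator: per-case abnormal fractions are drawn from
scaled Beta distributions whose quartiles exactly match each lesion class's
published median/IQR, nuclei are allocated to classes multinomially, and
2-D multichannel fields (DAPI + 53BP1, or DAPI + green/orange) are rendered
with Poisson + Gaussian noise and full per-nucleus ground truth, so the
whole pipeline is testable end to end.

## Worked example

Reproduce the MALT lymphoma association analysis from the packaged 19-case
table:

```sh
$ lymphofoci diagnose malt
6/19 cases (31.6%) above 33.6% cutoff; 5 of these t(11;18)+ (83.3%)
low group: 1 translocated, 9 wild, 3 no-signal
abnormal % vs translocation status: exact Wilcoxon p = 0.0145
therapy response: 2/5 (40.0%) high vs 7/9 (77.8%) low
```

Six of the 19 cases exceed the small-B-cell cutoff of 33.6% abnormal
nuclei; five of those six carry the t(11;18)(q21;q21) fusion, and the
abnormal fraction differs between translocated and non-translocated cases
(exact p = 0.0145). Responders to eradication/radiation therapy are rarer
in the high-abnormal group (40% vs 77.8%).

Simulate and score a follicular-lymphoma case from images:

```sh
$ lymphofoci simulate if --lesion FL1 --n-cases 1 --n-nuclei 100 \
      --nuclei-per-field 50 --seed 11 --out sim/
$ lymphofoci score-if --input sim/ --out scored/
$ cat scored/cases.csv
case_id,lesion_label,n_nuclei,pct_stable,pct_lowDDR,pct_highDDR,pct_largeFocus,pct_diffuse,abnormal_fraction
FL1_1,FL1,100,32.0,15.0,39.0,9.0,5.0,53.0
```

The recovered abnormal fraction (53.0%) sits on the generated truth for
this case (56.4% drawn from the FL1 distribution, realized over 100
nuclei) and far above the 27.2% follicular cutoff, so
`diagnose_lesion("follicular", 53.0)` labels it `FL-suspect`.

The same stages are available as library calls: `segment_nuclei` →
`detect_foci` / `diffuse_metrics` → `classify_nucleus` → `summarize_case`,
and `detect_signals` → `pair_fusions` → `call_nucleus_genotype` →
`summarize_fish_case` for FISH.

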