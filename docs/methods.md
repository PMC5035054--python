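# Methods

## The measurement model

The screen uses a bicistronic minigene reporter in which transcription drives
Firefly luciferase unconditionally, while Renilla luciferase is produced only
when a pair of alternative exons is spliced in-frame. One well therefore
yields a luminescence pair (R, F), and the ratio

    R/F ratio = Renilla / Firefly

reports splicing outcome normalized to transcriptional activity. Knockdown
effects, reporter induction differences and plate-to-plate drifts act
multiplicatively on luminescence, so all analysis happens in log2(R/F) space,
where they become additive and increases and decreases are treated
symmetrically.

## The screen statistic and decision rules

For each siRNA condition we take the arithmetic mean of log2(R/F) over its
valid replicate wells (a well is valid when Firefly > 0; wells with Renilla
= 0 have ratio 0 and are excluded from log-space means rather than
pseudocounted — a pseudocount would introduce an arbitrary scale parameter).
The effect of a siRNA is anchored to the controls of its normalization scope:

    delta              = mean log2(R/F | siRNA) − mean log2(R/F | negative control)
    normalized magnitude = |delta| / |mean log2(R/F | positive control) − mean log2(R/F | negative control)|

Decision rules, in order:

1. a siRNA is a **hit** when its normalized magnitude is ≥ 0.5 — at least
   half the positive-control effect, boundary inclusive;
2. a gene is a **hit** when at least two of its siRNAs are hits (genes with
   exactly two siRNAs can be hits);
3. a gene is a **triple hit** when it has ≥ 3 siRNAs and every one of them
   is a hit (two-siRNA genes can never be triple hits);
4. with direction concordance required (the default), hit siRNAs of one gene
   pointing in opposite directions demote the gene to not-hit and its
   direction is reported as "discordant" — opposite-signed effects from
   independent siRNAs against the same transcript are the signature of
   off-target artifacts. The requirement is configurable because the original
   screening practice on this point is not documented.

"Variation" is interpreted as magnitude: both R/F increases and decreases
can be hits, since validated regulators are known to push exon inclusion in
either direction.

Control anchoring defaults to per-plate controls, falling back to screen-wide
controls (with a logged warning) for plates without usable control wells;
`normalization_scope="screen"` forces pooled controls. When a siRNA's wells
span several plates, each plate contributes a control-anchored delta and a
positive-control effect, combined by a well-count-weighted mean; under the
packaged generator every siRNA sits on a single plate and this path is inert.

Two invariances follow directly and are enforced by tests: multiplying both
channels of a plate by a constant changes nothing (the ratio is unchanged
well by well), and multiplying every R/F on a plate by a constant changes no
delta (it cancels in the log-space subtraction).

## Splicing quantification formulas

For quantified product intensities (background-subtracted densitometry or
RT-(q)PCR product levels; no image analysis is performed here):

* **% splicing** = spliced / (unspliced + spliced) for one lane;
* **% post-transcriptional splicing** between an early (45 min) and a late
  (120 min) lane, after a transcription block at the early timepoint:
  (spliced₁₂₀ − spliced₄₅) / (unspliced + (spliced₁₂₀ − spliced₄₅)).
  The unsubscripted "unspliced" term is taken from the late lane — the lane
  actually being quantified at the endpoint; a pooled value would mix two
  reaction states. A negative spliced gain is measurement noise (spliced
  signal cannot decrease) and clamps to 0 with a warning. With zero early
  signal the formula reduces exactly to plain % splicing of the late lane;
* **% inclusion** = included / (included + skipped) for an alternative exon
  (a PSI-style measure);
* **transcription level** = 100 × (unspliced + spliced) / (same for a chosen
  reference lane); the reference maps to exactly 100 and the map is invariant
  to rescaling all intensities by a common factor.

All fractions are stored in [0, 1] and rendered ×100 in reports.

### Replicate comparison

`compare_to_control` compares treated vs control replicate fractions with a
two-sided Welch unequal-variance t test by default (the original significance
test behind the triplicate comparisons is unnamed; Welch assumes neither
equal variances nor, at n = 3, much else that any alternative would not).
An exact permutation mode enumerates all reassignments of the pooled values —
C(6,3) = 20 for triplicates, giving a two-sided p floor of 2/20 = 0.1. That
granularity is why the test suite cross-checks the permutation route against
an independently coded enumeration (exact agreement) and checks the Welch
default for rank agreement across fixtures rather than pointwise closeness:
no continuous p can match a 20-point distribution within 0.05 everywhere.
Both groups need ≥ 2 replicates; with two constant identical groups the test
degenerates to p = 1. No multiple-testing correction is applied, matching
per-exon reporting; users comparing many exons should correct downstream.

## Proteomics overlap

Factor evidence tables carry unique-peptide counts, % protein coverage and
log(e) search-engine confidence (more negative = more confident), plus one of
five frozen functional groups ("Chromatin Remodelling Factors", "Histone
PTMs regulators", "Transcriptional regulators", "Nucleosome components",
"Others"). Cross-list matching uses the NCBI Gene Id when present, else the
upper-cased symbol. The packaged reference table (83 rows) ships as plain
CSV. The hypergeometric upper-tail enrichment p attached when a gene
universe is supplied is an optional convenience — the underlying comparison
in the source experiments is qualitative — and factors outside the declared
universe are excluded before testing, since they could never overlap.

## Synthetic screens

The generator emulates the stated screen conditions and these are its
defaults, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| n_genes / composition | 375 genes; 345×3 + 30×4 siRNAs | the one 3/4 mixture matching the published totals (1155 siRNAs, average ≈ 3/gene) |
| n_replicates | 2 | duplicate wells per siRNA |
| plate_size | 96 | wells per plate |
| positive_control_effect | −1 log2 | the positive control halves R/F (a marked decrease; no published number exists, so it is a parameter) |
| noise_sd | 0.1 log2 | per-well log-normal noise on each luciferase |
| plate_factor_sd | 0.1 log2 | multiplicative per-plate R/F factor; a realistic plate effect that control anchoring must (and does) absorb |
| baseline_firefly / baseline_rf | 1e5 / 1.0 | arbitrary luminescence scale; the analysis is scale-free |
| controls per plate | 4 negative + 4 positive | occupy wells A1–A8; layout is a generator convention, the real plate layout being unpublished |

Per well: firefly = baseline × 2^N(0, noise_sd); R/F = baseline_rf ×
2^(effect + plate_factor + N(0, noise_sd)); renilla = R/F × firefly. Effect
tables map gene → per-siRNA log2 effects (scalar = all siRNAs), and the truth
table marks a gene as a true effector iff any of its siRNAs carries a nonzero
effect. All generators are driven by a single integer seed through numpy's
`default_rng` and are bit-reproducible.

What this emulates — multiplicative noise, plate effects, control anchoring,
partial-efficacy siRNAs — and what it does not: no spatial (edge/row) plate
artifacts, no siRNA off-target structure, no transfection-efficiency drift,
no luminescence saturation. Passing recovery tests therefore demonstrate
that the decision rules behave as designed under their own assumptions, not
that the original screen's error rates are reproduced; those depend on
unpublished raw data.

## Problem sizes and numerical choices

The oracle-equivalence suite runs 50 randomized screens of 8–30 genes; the
recovery suite runs 100 screens of 50 genes with 10 effectors at the
positive-control magnitude (pooled sensitivity ≥ 0.95, gene-level FPR ≤ 0.05
are the design targets, and 0.25× effectors must be called in well under half
of screens). These sizes keep the whole suite in seconds while giving
thousands of gene-level decisions per bound. Exact-arithmetic checks
(hypergeometric tail vs combinatorial enumeration, permutation p vs
enumeration) use tolerances of 1e-12 and exact equality respectively.
Degenerate inputs have defined behavior throughout: zero-total lanes raise,
zero Renilla leaves the log domain, coincident control means raise a
degenerate-control error naming the plate, and empty hit tables refuse to
serialize.

## Known limitations

* The hit rule is a percent-of-control threshold by construction; no
  B-score/SSMD-style machinery is provided because none is defined for this
  design.
* Gene-level voting treats siRNAs symmetrically; knockdown-efficiency
  information, if available, is not used.
* The screen-wide control fallback assumes plates are exchangeable up to a
  multiplicative factor; a plate with both missing controls and a strong
  additive artifact would be mis-anchored (and is not modeled).
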