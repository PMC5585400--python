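# tandem5ss

Analysis of **competing tandem 5' splice sites** — loci where two donor
sites a handful of nucleotides apart share one acceptor, so that choosing the
upstream (*intron-distal*) donor truncates the exon while the downstream
(*intron-proximal*) donor yields the canonical transcript. Such loci are a
common way for a single exon to encode two protein isoforms, and their
balance is often set by an SR protein bound immediately upstream of the donor
pair.

The package is for computational biologists who have already summarized a
perturbation experiment — isoform-diagnostic read counts per locus and
condition, plus per-base CLIP tag coverage for the candidate regulator — and
want the downstream statistics:

* **PSI inference** — the inclusion fraction psi (proximal-donor usage) has
  posterior Beta(n_proximal + 1, n_distal + 1) under a uniform prior and
  equal effective lengths; the general case uses
  p(psi) = psi·l_inc / (psi·l_inc + (1−psi)·l_exc) on a deterministic grid.
  Two-condition comparisons report Δψ = E[ψ_kd] − E[ψ_ctrl] and the Bayes
  factor BF = m(L₁)m(L₂) / m(L₁L₂) for "psi differs" vs "psi equal", then the
  standard filter: ≥1 inclusion read, ≥1 exclusion read, |Δψ| ≥ 0.2, BF ≥ 10.
* **Classification** — significant events split by sign of Δψ into
  distal-activated (inclusion fell) vs proximal-activated.
* **CLIP metaprofiles** — strand-aware 400-nt windows (r = −200..+199, r = 0
  at the donor's first intronic base), per-event density d_r = c_r / Σc,
  cross-event mean ± SE per class and anchor, and an eight-section (50 nt)
  argmax report; section 4, r ∈ [−50, 0), is the exonic 50 nt immediately
  upstream of the donor.
* **Motif scoring** — additive PWM scanning for ESEs (the published ESEfinder
  SRSF1 heptamer matrix ships with the package), donor 9-mer scoring
  (weight-matrix log-odds; maximum-entropy and donor-frequency scores via
  external lookup tables), and block-scanning mutant design with Δ(max ESE)
  annotation.
* **Synthetic cohorts** — a seeded generator producing event tables, counts
  and CLIP coverage with known ground truth, so the whole pipeline is
  testable end to end without any downloads.

See `docs/methods.md` for the model details and design choices.

## Worked example

Simulate a 200-event cohort (default conditions: depth 200, effect size 0.4,
70/20/10 class mix, CLIP peaks 25 nt upstream of the distal donor in
distal-activated events) and run the full chain:

```sh
tandem5ss simulate --outdir demo --seed 7
tandem5ss psi --counts demo/counts.tsv --out demo/psi.tsv
# -> 200 events compared, 179 significant -> demo/psi.tsv
tandem5ss classify --results demo/psi.tsv --out demo/classified.tsv
# -> 200 events: 134 distal_activated, 45 proximal_activated, 21 unchanged
tandem5ss metaprofile --bedgraph demo/clip.bedgraph --events demo/events.tsv \
    --classified demo/classified.tsv --outdir demo/meta
```

The per-event results hold everything the filter saw:

```
event_id  psi_ctrl  psi_kd    delta_psi  bayes_factor  ...  significant
ev00000   0.640625  0.222826  -0.417799  1.61205e+14   ...  True
```

ev00000's inclusion fell by 0.42 with overwhelming evidence (BF ≈ 1.6e14),
so it is classified distal-activated. The cohort recovers its generating mix
(134/45/21 against a 140/40/20 expectation), and the section report for the
distal-activated class shows the planted binding peak where it was placed —
124 of 134 events have their coverage maximum in section 4, the 50 nt
immediately upstream of the distal donor:

```
section  r_start  r_end  n_argmax
4        -50      0      124
```

Motif scanning with the packaged SRSF1 matrix flags the known strong ESE:

```sh
tandem5ss scan-ese --seq TTGGGACCATT
# start  window   score  is_max
# 2      GGGACCA  1.74   1
```

One-shot orchestration (`tandem5ss run --config run.json`) runs
simulate → psi → classify → metaprofile and writes a manifest with per-stage
record counts and SHA-256 checksums; the same config and seed reproduce the
artifacts byte for byte.

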