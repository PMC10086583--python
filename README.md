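# hrdscape

Genomic-scar scoring and chromosomal-instability analysis for sarcoma
copy-number profiles: quantify HRD*ness* (homologous recombination
deficiency) from allele-specific copy-number segments, derive the HRR-CIN
score, infer classification cut-offs from bimodal cohorts, build oncoprint
alteration matrices, score the SARC-HRD expression signature, and model
two-drug dose-response synergy.

## Who this is for

Cancer genomics analysts working with segmented copy-number data (ASCAT /
EaCoN / GDC allele-specific segments), who need HRD scar scores and CIN
features without re-running segmentation, plus the downstream cut-off and
classification machinery used to call tumours HRD-high vs HRD-low.

## The scores

For a tumour's allele-specific copy-number profile (per-segment major and
minor allele counts n_A ≥ n_B):

* **LOH** — number of loss-of-heterozygosity regions (n_B = 0, n_A ≥ 1)
  longer than 15 Mb that do not span a whole chromosome.
* **LST** — large-scale state transitions: chromosomal breaks between
  adjacent regions of ≥ 10 Mb within one chromosome arm, after removing
  interstitial segments shorter than 3 Mb and allowing an inter-breakage
  distance of at most 3 Mb.
* **TAI** — telomeric allelic imbalances: regions with n_A ≠ n_B that
  reach a telomere without crossing the centromere and without covering
  the whole chromosome.
* **HRD score** = LOH + LST + TAI (unweighted, linear sum).
* **HRR-CIN** — chromosomal instability restricted to a catalog of 70
  genes of the homologous-recombination-repair pathway: each gene
  contributes +1 if hit by a copy-number gain and +1 if hit by a loss.
* **FGA / aneuploidy** — fraction of the genome gained or lost (L2R
  thresholds ±0.1, high-level events at ±0.7), and chromosomes with more
  than 90% of their length gained or lost.

Cut-offs are inferred, not assumed: a two-component Gaussian mixture is
fitted to the bimodal HRR-CIN distribution, the cut-off is the weighted
density crossing between the modes (posterior probability 0.5, with a
parametric-bootstrap CI), and the HRD score cut-point is then the Youden
maximiser (J = sensitivity + specificity − 1) of the ROC of HRD against
the mixture-derived status. Published fixed thresholds (HRD ≥ 32, LOH
≥ 10) are available for cross-cohort application.

Drug response: viability is normalised to untreated controls, monotherapy
curves are fitted with the four-parameter logistic
v(x) = bottom + (top − bottom)/(1 + (x/IC50)^hill), and two-drug matrices
are scored against ZIP, Loewe, Bliss and HSA reference models
(score = 100 × mean excess of observed over expected inhibition;
positive = synergy).

## Worked example

The `analysis/` scripts run the full workflow on a simulated cohort of
120 samples (60 HRD-high, 60 HRD-low):

```
$ python analysis/01_simulate_cohort.py
wrote cohort of 120 samples (60 HRD-high, 60 HRD-low) to results/sim
$ python analysis/02_score_scars_and_cin.py
scored 120 samples; truth recovery 100.0%
$ python analysis/03_infer_cutoffs.py
HRR-CIN mixture means 7.9 / 50.6; cutoff 20.6 (95% CI 18.3-23.1)
HRD cut-point 16.5 (AUC 1.000); LOH cut-point 5.0 (AUC 1.000)
HRD status recovers simulated groups at 100.0%
$ python analysis/04_signature_scores.py
signature score: HRD-high mean 0.67, HRD-low mean -0.67, AUC 1.000
```

Reading this: every implanted scar event was recovered exactly (the
generator places events so they cannot interfere); the mixture found the
two HRR-CIN modes near their simulated means (8 and 50); the inferred
HRR-CIN cut-off of 20.6 separates them; dichotomising the HRD score at
the Youden-optimal 16.5 assigns every sample to its true group; and the
SARC-HRD signature (10 HRR genes up-shifted by one log2 unit in HRD-high
samples) separates the groups with AUC 1.0.

The same operations are exposed as a CLI:

```
hrdscape score  --segments ascn.tsv --genome hg38 --out scars.tsv
hrdscape cin    --segments gene_cn.tsv --genome hg38 --out cin.tsv
hrdscape cutoff --features features.tsv --score-col hrr_cin --biomarker-col hrd --out cutoffs.json
hrdscape run    --segments ascn.tsv --gene-cn-segments gene_cn.tsv --outdir out/
```

## Layout

```
src/hrdscape/        library: reference_io, scar_signatures, cin_features,
                     cutoff_inference, alterations, expression_signature,
                     drug_response, synthetic, pipeline, cli
analysis/            numbered drivers of the cohort workflow
tests/               pytest suite incl. brute-force oracles
docs/methods.md      models, parameters, numerical choices, limitations
```
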