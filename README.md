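# splicesel

Weak selection inference at splice sites from substitution-rate ratios.

## The problem

Donor (`exon|GTaagt`) and acceptor (`(y)nCAG|exon`) splice sites are short
functional sequences in which each position is usually occupied by one or
two *consensus* (Cn) nucleotides, yet a substantial fraction of sites carry
*nonconsensus* (Nc) nucleotides, and the non-canonical positions are not
perfectly conserved between species.  If the fitness differences between Cn
and Nc alleles are of order 1/N<sub>e</sub>, such positions undergo a
nearly neutral turnover: Cn→Nc substitutions are weakly deleterious
(negative selection) and Nc→Cn substitutions weakly advantageous (positive
selection), and both leave a quantitative signature in lineage-specific
substitution frequencies.

`splicesel` measures that signature.  Given triplet alignments
(reference, sister, outgroup) of splice-site regions, it

1. reconstructs the reference/sister ancestor by maximum parsimony and
   polarizes substitutions onto the reference branch;
2. computes the class substitution frequencies q(Cn→Nc) and q(Nc→Cn) per
   position, against nucleotide-matched neutral expectations taken from
   adjacent-intron and fourfold-degenerate-site controls filtered by a
   neutrality score;
3. inverts the Kimura fixation-rate ratio
   r(S) = S / (1 − e<sup>−S</sup>), with S = 4N<sub>e</sub>s, to estimate
   the scaled selection coefficient at each position, with exact
   (Clopper–Pearson) confidence intervals;
4. measures multispecies conservation depth L (in Ks units) of specific
   nucleotides (c<sub>nuc</sub>) and of whole Cn/Nc classes
   (c<sub>set</sub>) relative to neutral controls,
   c = (obs − exp)/exp, with column-bootstrap CIs; and
5. summarizes genome-wide drift load — the summed selection coefficient
   against all fixed Nc alleles, n<sub>SS</sub> · mean(Nc) · s.

Because the real inputs (genome-scale annotations, multiple alignments,
conservation tracks) are bulky, the package bundles an origination–fixation
simulator with known ground-truth selection that emulates the full study
design — triplet ensembles, matched neutral controls with synthetic
neutrality scores, and deeper multispecies panels — so every stage is
testable end to end.

## Worked example

Simulate 20,000 donor sites under homogeneous selection S = 4N<sub>e</sub>s
= −2 favoring the consensus, then recover S from the substitution
frequencies:

```python
from splicesel import (SimParams, simulate_triplet_ensemble, count_substitutions,
                       reconstruct_controls, neutral_rates, estimate_selection,
                       ConsensusTable)
from splicesel.substitution import pooled_class_counts, CN_TO_NC, NC_TO_CN

consensus = ConsensusTable.default()
params = SimParams(n_sites=20000, site_type="donor", S_profile=-2.0, seed=1)
ensemble = simulate_triplet_ensemble(params)
counts = count_substitutions(ensemble, consensus)
neutral = neutral_rates(reconstruct_controls(ensemble.controls))
for direction in (CN_TO_NC, NC_TO_CN):
    pooled, q_exp = pooled_class_counts(counts, neutral, consensus, direction)
    est = estimate_selection(pooled, q_exp)
    print(f"{direction}: q = {pooled.q:.5f}, q_exp = {q_exp:.5f}, "
          f"4Nes = {est.S_hat:.2f} [{est.S_low:.2f}, {est.S_high:.2f}]")
```

prints

```
Cn->Nc: q = 0.00853, q_exp = 0.02665, 4Nes = -1.97 [-2.07, -1.86]
Nc->Cn: q = 0.02531, q_exp = 0.01128, 4Nes = 1.91 [1.70, 2.13]
```

Consensus alleles are lost at roughly a third of the neutral rate and
gained at roughly 2.3 times the neutral rate, and inverting the fixation
ratio recovers the simulated S ≈ −2 (negative selection protecting Cn) and
S ≈ +2 (positive selection favoring Cn where Nc is fixed).  With
`per_locus_s(S, Ne)` these convert to per-locus selection coefficients
(≈ 2.5 × 10⁻⁵ at N<sub>e</sub> = 10⁴; ≈ 2.5 × 10⁻⁷ at 10⁶), and
`drift_load(150000, 7.10, 2e-5)` gives the summed load ≈ 21 for an
acceptor-site inventory carrying 7.1 Nc nucleotides per site on average.

## Command line

```bash
splicesel run-all config.yaml outdir/     # full pipeline + manifest
splicesel simulate config.yaml simdir/    # write FASTA + site/control TSVs
splicesel extract anno.gff3 genome.fa sites.tsv --alignment sister=sis.fa
splicesel count sites.tsv counts.tsv      # parsimony + substitution counts
splicesel infer config.yaml outdir/       # counting + selection inference
splicesel conserve config.yaml outdir/    # multispecies conservation stage
```

`config.yaml` holds a mapping of `RunConfig` fields (mode, seed, ensemble
sizes, thresholds); every analysis threshold (neutrality-score cutoff 0.6,
alpha 0.05, 1000 bootstrap trials, strength tertiles) is a configurable
default.  All outputs are TSV tables plus a JSON manifest with the config
hash, so identical configs reproduce identical bytes.

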