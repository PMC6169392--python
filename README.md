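# codonlrt

Codon-level likelihood ratio tests of selective constraint for predicting
deleterious amino acid variants in plant (or any) genomes.

## The problem

Most amino acid changes that alter a phenotype do so by damaging a conserved
protein position.  Given an in-frame CDS alignment of a gene against its
homologs and a phylogeny, `codonlrt` tests each codon of interest for
evolutionary constraint and converts the result into a probability that an
amino acid substitution there is deleterious.  It is aimed at researchers
benchmarking variant-effect predictors or annotating candidate mutations in
species where the popular human-centric tools have no precomputed resources —
all it needs is an alignment, a tree, and a variant list.

## The test

Codon evolution is modelled as an MG94-type Markov process on the 61 sense
codons with F1x4 frequencies: single-nucleotide changes occur at rate
π(target), multiplied by ω = dN/dS when nonsynonymous.  The generator is
scaled so branch lengths are expected synonymous substitutions per codon site
(dS) — synonymous divergence is the internal neutral clock.  Per gene, branch
lengths and a gene-wide ω are estimated by maximum (weakly penalized)
likelihood, with per-branch dS capped at 3.  At each tested codon:

    H0:  dN = dS        (ω fixed at 1)
    H1:  dN = ω·dS      (ω free in [1e-6, 50])

with branch lengths fixed at the gene fit; the statistic 2·ΔlnL is referred
to χ²₁.  Each variant is scored twice — *unmasked*, and *masked* with the
entire query sequence treated as missing so the reference allele cannot bias
its own conservation signal.  The capped results (p ≥ 1e-16, ω̂ ≤ 10) feed
two fixed logistic models:

    unmasked:  logit(p_del) = −2.407 − 0.2139·log10(p) − 0.2056·ω̂ + 0.07368·Rn − 0.1236·An
    masked:    logit(p_del) = −2.453 − 0.1904·log10(p) − 0.1459·ω̂ + 0.2199·max(Rn,An) − 0.2951·|Rn−An|

where Rn and An count alignment rows carrying the reference and alternate
amino acid at the column.  The package also ships the evaluation machinery
used to benchmark such predictors (ROC/AUC with stratified bootstrap CIs,
95%-specificity calls, minor-allele-frequency-class enrichment, cumulative
agreement, disagreement clustering with bootstrap support), a per-codon
combination rule for nucleotide-level conservation scores, a logistic
ensemble combiner, and a forward simulator of codon alignments with
site-specific ω that makes the whole system testable without external data.

## Worked example

Simulate a small benchmark gene (8 species, 120 codons, total dS = 12, five
variants placed at constrained sites and five at neutral sites), run both LRT
modes, and score:

    codonlrt simulate --n-codons 120 --n-tips 8 --total-ds 12 \
        --n-deleterious 5 --n-neutral 5 --seed 7 --out-prefix demo
    codonlrt predict --alignment demo.fasta --tree demo.nwk \
        --variants demo.variants.tsv --query T1 --out demo.pred.tsv
    codonlrt score --predictions demo.pred.tsv --out demo.scored.tsv

`demo.scored.tsv` then contains (abridged):

       gene  codon_pos ref_aa alt_aa    label  p_value  constraint  Rn  An  prob_unmasked  prob_masked
    simgene         75      H      D positive   0.0127       0.244   3   0          0.138       0.0801
    simgene         68      A      G positive 1.14e-06       1e-06   7   0           0.35        0.122
    simgene        118      P      R positive  0.00514       0.175   2   0          0.141       0.0983
    simgene          2      G      R negative    0.987       0.983   2   0         0.0787       0.0189
    simgene        106      K      T negative    0.712        1.56   1   1         0.0603       0.0651

Variants planted at constrained sites come back with small LRT p-values and
site ω̂ well below 1 — the column is under purifying selection — and
correspondingly higher deleterious probabilities; variants at neutral sites
get p ≈ 1 and ω̂ ≈ 1.  The probabilities are not calibrated frequencies; they
are ranking scores whose operating threshold is set on a benchmark (for
example at 95% specificity via `codonlrt evaluate`).

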