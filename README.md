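# s1drive

Genetics of the *S1* gamete killer–protector system of African rice
(*Oryza glaberrima*), the locus that causes hybrid sterility and
transmission ratio distortion in crosses with Asian rice (*O. sativa*).

The African *S1-g* allele carries three closely linked genes —
*S1A4*, *S1TPR*, *S1A6* — that act as a selfish tripartite element.
The killer arms **sporophytically**: a diploid plant whose combined
genotype carries the full component set {A4, TPR, A6} (even spread over
unlinked transgene insertions) produces a sterility signal.
Protection is **gametophytic**: a haploid gamete survives only if it
itself carries TPR; unprotected gametes abort with probability *k* per
sex (*k* = 1 is complete killing). The Asian *S1-s* allele carries only
the truncated, inert *S1TP*, so in *S1-g/S1-s* heterozygotes the
*S1-s* gametes die and *S1-g* is over-transmitted — a classic gamete
killer drive.

`s1drive` implements this model end to end:

- **`s1drive.model`** — alleles as component sets, diploid genotypes over
  unlinked loci, killer arming, gamete enumeration, viability selection,
  fertility prediction (`predict_fertility`), and progeny distributions
  (`cross_progeny`). For a cross with per-gamete driver survival
  probability 1 and non-driver survival 1 − *k*, the surviving driver
  gamete fraction from a heterozygote is 1/(2 − *k*).
- **`s1drive.segregation`** — Pearson χ² goodness-of-fit of observed
  genotype-class counts against model expectations, transmission ratios
  with Wilson 95% intervals, and maximum-likelihood estimation of *k*
  from observed segregation (multinomial likelihood, profile-likelihood
  CI), including pooled scoring schemes (e.g. dominant markers).
- **`s1drive.drive`** — deterministic and Wright–Fisher multi-generation
  allele-frequency trajectories under selfing or random mating.
- **`s1drive.haplotypes`** — classification of accessions' *S1*
  haplotype structures from the 7-site *S1TPR*/*S1TP* SNP panel (site 7
  is the C→A stop-gain) and breadth-of-coverage presence/absence calls
  for *S1A4*/*S1A6* from `samtools depth`-style per-base profiles.
- **`s1drive.simulate`** — synthetic progeny count tables, Poisson depth
  profiles, and whole accession panels with ground truth, so every
  stage is testable without any sequencing data.

## Worked example

Self the F1 of a hemizygous *S1TPR* transgene line crossed to a near
isogenic line carrying *S1-g* — an *S1* heterozygote with one unlinked
protector copy:

```python
>>> import s1drive as sd
>>> model = sd.default_model()          # S1 + transgene loci, k = 1
>>> f1 = model.genotype("f1_protected") # S1:(g,s) + TPRt:(T,-)
>>> f = sd.predict_fertility(f1, model.spec)
>>> round(f.pollen_fertility, 2), round(f.spikelet_fertility, 2)
(0.75, 0.75)
>>> f2 = sd.cross_progeny(f1, f1, model.spec)
>>> {k: round(v, 4) for k, v in f2.marginal("S1").items()}
{'gg': 0.4444, 'gs': 0.4444, 'ss': 0.1111}
>>> {k: round(v, 4) for k, v in f2.marginal("TPRt").items()}
{'--': 0.1111, 'T-': 0.4444, 'TT': 0.4444}
```

The F1 is 75% fertile (the *S1-g* gametes plus the protected half of
the *S1-s* gametes survive), and both the native locus and the unlinked
transgene segregate 4:4:1 in the F2 — the hallmark of gametophytic
rescue acting independently at each locus. One selfed generation with
*k* = 0.95 takes the driver from frequency 0.5 to:

```python
>>> state = sd.PopulationState.monomorphic(model.genotype("f1_plain"))
>>> nxt = sd.deterministic_step(state, model.spec.with_abort(0.95))
>>> round(nxt.allele_frequency("S1", "g"), 2)
0.95
```

The same stages are available from the shell:

```sh
s1drive predict-cross --mother f1_protected --out progeny.tsv
s1drive simulate-data --kind panel --seed 7 --out-dir panels/
s1drive classify-haplotype --run-dir panels/run_7 \
    --bed panels/run_7/genes.bed --out calls.tsv
```

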