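# flypsd

Forward population-genetic simulation of **polygenic sex determination
(PSD)** in the house fly, *Musca domestica*.

House fly populations segregate three young proto-sex chromosomes at once:
two proto-Y chromosomes — Y^M and III^M, each carrying the male determiner
*Mdmd* — and one proto-W, IV^F, carrying the epistatically dominant female
determiner *Md-tra^D* (any IV^F copy forces female development regardless
of *Mdmd*). With three segregating pairs there are 18 reachable diploid
genotypes (10 female, 8 male). Whether such a polymorphism is a stable
equilibrium or a transient between monogenic systems depends on the
selection pressures on the proto-sex chromosomes — and, as this package
lets you explore, on the *dominance* of those fitness effects.

## The model

Each derived chromosome *j* gets a sex-specific selection coefficient
*s<sub>ij</sub>* ~ Uniform(−1, 1). Single-pair genotype fitness follows one
of four dominance schemes (columns = copies of the derived allele):

| scheme | 0 | 1 | 2 |
|---|---|---|---|
| additive, *s*>0 | 1−*s* | 1−*s*/2 | 1 |
| additive, *s*<0 | 1 | 1+*s*/2 | 1+*s* |
| dominant, *s*>0 | 1−*s* | 1 | 1 |
| dominant, *s*<0 | 1 | 1+*s* | 1+*s* |
| recessive, *s*>0 | 1−*s* | 1−*s* | 1 |
| recessive, *s*<0 | 1 | 1 | 1+*s* |
| overdominant (males), any *s* | 1−\|*s*\| | 1 | 1−\|*s*\| |

Under the overdominant scheme females use the additive rows; the IV^F pair
has a single carrier state (IV/IV^F) with fitness 1−*s*. Multi-chromosome
genotype fitness is the product of the three single-pair values.

One generation of the deterministic recursion applies selection as parental
weights within each sex, pools fitness-weighted Mendelian gametes, unites
eggs and sperm at random, and assigns zygote sex by the epistatic rule. PSD
is *maintained* when all three derived chromosomes stay above 0.1% of their
chromosome pools after 1000 generations; a proto-Y *fixes* when it exceeds
99.9%. A Wright–Fisher layer (multinomial resampling of N zygotes per
generation) adds drift, with neutral runs as drift-only controls compared
by Fisher's exact test. Sexual antagonism is summarised by ρ<sub>MF</sub>,
Spearman's rank correlation of fitness across the eight male–female
genotype pairs that differ only by one IV^F copy.

## Worked example

```bash
$ flypsd screen --seed 1 --arrays 2000 --scheme additive --scheme overdominant --out runs/demo
additive: 3.95% of arrays maintain PSD
overdominant: 44.00% of arrays maintain PSD
```

With additive fitness effects fewer than 5% of random selection-coefficient
sets keep all three proto-sex chromosomes polymorphic for 1000 generations;
with male-overdominant effects (heterozygote advantage of the proto-Ys in
males) more than 40% do. The same screen from the library, plus the
antagonism and fitting summaries:

```python
>>> import flypsd as fp
>>> plan = fp.ExperimentPlan(n_arrays=2000, seed=1)
>>> scr = fp.run_screen(plan, "overdominant")
>>> scr.maintenance_fraction
0.44
>>> scr.table.loc[scr.table.psd_maintained, "rho_mf"].median()
-0.074
>>> fits = fp.run_fit(scr)        # top-k rejection against observed frequencies
>>> len(fits["CA"].array_ids), float(fits["CA"].mse[0])
(880, 0.0019286661232000325)
```

The median intersexual fitness correlation among maintaining overdominant
arrays is near zero (−0.07): male heterozygote advantage maintains the
polymorphism without negative fitness correlations across the sexes. The
fitting step ranks maintaining arrays by mean squared error between
simulated and observed chromosome frequencies; the shipped CA/NC/NY tables
are synthetic placeholders within the published ranges (see
`flypsd.fitting.OBSERVED_PLACEHOLDERS`), and real tables can be supplied as
YAML via `flypsd fit --observed`.

Other subcommands: `flypsd table` (the 18-genotype table), `longrun`
(million-generation reclassification), `finite` (Wright–Fisher with
drift controls), `summarize`.

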