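# File formats

All files are tab-delimited text, 6 significant digits for reals, `NA`
for missing values.  Every file written by `triomr` is readable by its
own readers.

## Dosage matrix

Rows = samples, columns = variants; first column `sample_id`, header row
carries variant ids.  Hard calls are {0, 1, 2}; imputed dosages (any real
in [0, 2]) require `allow_imputed=True` / the relevant CLI flag.

```
sample_id	rs1	rs2
F000000_M	0	2
F000001_M	1	1
```

## Pedigree (FAM-like)

One row per trio.  Rows with a missing member are dropped with a warning;
a child in two families is an error.

```
family_id	child_id	father_id	mother_id
F000000	F000000_C	F000000_F	F000000_M
```

## Phenotype / covariate table

Rows keyed by `family_id`; the simulator writes `exposure_mother`,
`exposure_father`, `outcome_child`; covariates go in a parallel table
with columns `cov0`, `cov1`, …

```
family_id	exposure_mother	exposure_father	outcome_child
F000000	1.2341	-0.4412	0.8832
```

## GWAS summary statistics

Canonical columns (rename via a column map): `variant_id`, `chromosome`,
`position`, `effect_allele`, `other_allele`, `beta` (the per-allele
weight), `se`, `p_value`, `effect_allele_freq`.  `variant_id`, both
alleles and `beta` are required.

```
variant_id	chromosome	position	effect_allele	other_allele	beta	se	p_value	effect_allele_freq
rs1	1	1000	G	A	0.02	0.003	1e-12	0.31
```

## SNP-outcome association table

Emitted by `estimate_snp_outcome_associations` / the `snpmr` subcommand;
one row per variant with the trio-adjusted parental coefficient.

```
variant_id	beta	se	n
snp1	0.198	0.012	4000
```

## VCF (optional)

Minimal VCFv4.2 export with a `GT` field (`0/0`, `0/1`, `1/1` from
dosages 0/1/2); ingestion reads `DS` if present, else `GT`, and rejects
multiallelic records.

## Simulation config (YAML)

Keys mirror `SimConfig` fields; unknown keys are rejected.

```yaml
n_couples: 1000
n_snps: 5
allele_freqs: 0.5
assortment_phi: 0.6
seed: 7
```
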