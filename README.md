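# taxfun

Biomass-constrained estimation of biological-function (GO-term) abundances
across the full taxonomic lineage of microorganisms identified in
mass-spectrometry-based metaproteomics.

Shared confidently identified peptides — peptides compatible with several
related species — are the central difficulty: the common lowest-common-ancestor
(LCA) assignment pushes their evidence to internal taxonomy nodes and discards
the information carried by the unique peptides. `taxfun` instead runs a
two-stage expectation-maximization:

1. **Stage 1 — taxon biomass.** EM over mixture weights `p(t)` per identified
   taxon, weighting each peptide by its MS1 extracted-ion-chromatogram area
   times its spectral count. The probabilities sum to 1 over identified taxa.
2. **Stage 2 — function abundance.** Per GO aspect, EM over the conditionals
   `p(k|t)` with `p(t)` held fixed, so the joint `p(k|t)p(t)` sums exactly to
   each taxon's biomass (a reserved `UNANNOTATED` sink term keeps mass
   conserved for peptides from unannotated proteins).
3. **Lineage aggregation.** Species-level tables are summed up to each of the
   seven canonical ranks (root, phylum, class, order, family, genus, species);
   the set of unique GO ids is identical at every level by construction.

The package also provides the LCA baseline (per-peptide LCA assignment,
normalized taxon abundances, GO-term spectral-count abundances, and the
0.5%-of-taxon-specific-peptides filter), protein clustering/unclustering,
confidence filtering, evaluation statistics (sensitivity/PFD,
overlap-coefficient matrices, log2-fold-change error metrics, quasi-gold
standards), and a synthetic community generator with known ground truth.

## Testing

```sh
python -m pytest -q tests/
```

The suite includes unit tests with independent oracles (grid-search likelihood
maximization, brute-force closures and scans), property tests, and
`tests/test_acceptance.py` covering the acceptance criteria end to end. The
whole run takes well under a minute.

## Command-line usage

```sh
# generate a 4-species 1:2:2:4 community with 20% genus-shared peptides
taxfun simulate --out-dir fixture --seed 1 --ratios 1:2:2:4 --noise-sigma 0.5

# EM path: biomass.tsv + abundance.tsv at all seven taxonomic levels
taxfun run --out-dir out \
    --peptides fixture/peptides.tsv --proteins fixture/proteins.tsv \
    --annotations fixture/annotations.tsv --taxonomy fixture/taxonomy.tsv

# LCA baseline path: lca.tsv, nta.tsv, ba.tsv
taxfun lca --out-dir out-lca \
    --peptides fixture/peptides.tsv --proteins fixture/proteins.tsv \
    --annotations fixture/annotations.tsv --taxonomy fixture/taxonomy.tsv

# sensitivity / proportion of false discoveries of a reported term set
taxfun evaluate --out-dir out-eval --reported reported.tsv --gold gold.tsv

# overlap-coefficient matrix across term-set files
taxfun compare --out-dir out-cmp a.tsv b.tsv c.tsv
```

All commands accept `--config FILE` with flat `key=value` pairs (defaults:
`peptide_evalue_cutoff=1`, `taxon_evalue_cutoff=0.01`, `protein_pfd=0.01`,
`protein_evalue_cutoff=1`, `cluster_overlap=0.8`, `em_tol=1e-10`,
`em_max_iter=2000`, `ev_threshold=2`, `unipept_filter_fraction=0.005`,
`seed=0`). Every run writes a `provenance.json` with the configuration,
package version and SHA-256 checksums of the inputs; reruns with the same
inputs and seed are checksum-identical.

## File formats

UTF-8, tab-separated, single header row:

| file | columns |
| --- | --- |
| `peptides.tsv` | `peptide, evalue, ms1_area, spectral_count, sample_id` |
| `proteins.tsv` | `accession, taxon_id, evalue, peptides` (semicolon-joined) |
| `annotations.tsv` | `accession, go_id, aspect` (GAF 2.2 also readable) |
| `taxonomy.tsv` | `taxon_id, name, rank, parent_id` (NCBI taxdump also readable) |
| `biomass.tsv` | `sample_id, level, taxon_id, biomass` |
| `abundance.tsv` | `sample_id, level, taxon_id, taxon_name, aspect, go_id, abundance` |

`spectral_count` carries a peptide's redundant occurrence count; repeated
identifications are one row.

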