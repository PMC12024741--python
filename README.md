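# endoqc

Quality evaluation for degraded short-read alignments (hair shafts, old
museum material, other low-input samples): endogenous-content metrics,
read-size-stratified mapping trends, terminal deamination damage profiling,
and normality-gated group comparisons — plus a synthetic degraded-read
generator with per-read ground truth so every stage is verifiable by
parameter recovery.

## What it computes

| Quantity | Definition |
| --- | --- |
| `R_m` | mapped / total cleaned primary reads (endogenous DNA proportion) |
| `R_m0` | multi-mapped (MAPQ 0) / mapped reads |
| `A_L` | mean read length (bp) |
| size bins | `R_m`/`R_m0` stratified into 10-bp read-length bins, midpoint convention, with an OLS trend fit over bin midpoints |
| damage profile | per-position C→T (5′) / G→A (3′) substitution rates over a 25-bp window at each fragment end, reconstructed from MD tags or a reference FASTA |
| `N_db` | consecutive positions from the terminal base with damage rate strictly above the window mean |
| `R_dm` | maximum per-position damage rate in the window |
| `CV` | sample SD / mean across samples |
| comparisons | Shapiro–Wilk-gated choice of (paired) t-test vs Wilcoxon rank-sum / signed-rank, two-sided, α = 0.05 |

Inputs are aligned reads in SAM (parsed in-repo) or BAM (via pysam), with
MD tags or an accompanying reference FASTA. Secondary/supplementary records
are excluded from denominators; duplicates are counted by default
(configurable).

## CLI

```sh
# per-sample metrics for one alignment file
endoqc metrics sample.sam

# terminal damage profile + N_db / R_dm summary (both ends)
endoqc damage sample.sam --damage-window 25 -o sample_damage

# synthetic fixture with known truth (single sample ...)
endoqc simulate --out-dir sim --seed 1 --n-reads 10000 \
    --endogenous-fraction 0.8 --d0-3p 0.3 --decay 0.5

# ... or a multi-sample study fixture
endoqc simulate --out-dir fx --scenario hair_type_contrast --seed 1

# full study workflow from a YAML config
endoqc study fx/study.yaml --out-dir report
```

`endoqc study` writes a deterministic report bundle —
`sample_metrics.tsv`, `size_bins.tsv`, `trend_fits.tsv`,
`damage_profiles.tsv`, `damage_summaries.tsv`, `comparisons.tsv` and a
`manifest.json` with per-file SHA-256 checksums; reruns with the same
inputs are byte-identical.

A study config names samples with group labels and the comparisons to run:

```yaml
schema: endoqc-study-v1
reference: ref.fasta
options: {seed: 1, damage_window: 25, bin_step: 10, min_reads: 100, alpha: 0.05}
samples:
  - {sample_id: H01, path: H01.sam, groups: {hair_type: light}}
  - {sample_id: H09, path: H09.sam, groups: {hair_type: high}}
comparisons:
  - {label: r_m_by_hair_type, variable: hair_type, metric: r_m, paired: false}
```

## Package layout

```
src/endoqc/
  records.py       alignment record model, CIGAR helpers
  alignment_io.py  SAM/BAM/FASTA/TSV readers and writers
  qc_metrics.py    R_m, R_m0, A_L; size bins; trend fits
  damage.py        MD/CIGAR pairwise reconstruction; damage profiles,
                   N_db / R_dm / CV
  group_stats.py   Shapiro–Wilk gate, t / Wilcoxon tests, mean ± SD
  synthetic.py     degraded-read simulator + study fixtures with truth
  study.py         study config, report bundle orchestration
  cli.py           click CLI (metrics / damage / simulate / study)
```
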