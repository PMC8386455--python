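# rhodoquant

Identification, classification and quantification of **proteorhodopsin
(PR)** genes and transcripts in marine microbial meta-omic and qPCR
data, with a ground-truthed synthetic-community generator for testing
every estimator.

Proteorhodopsin is a single-protein, retinal-binding, light-driven
proton pump — the simplest phototrophic strategy in the ocean. Two
questions drive this package: *what fraction of a bacterial community
carries a PR gene*, and *which spectral variants (blue- vs
green-absorbing) are present and actually transcribed*. It is written
for microbial ecologists who already have assembled genes, per-gene read
or transcript counts, and/or qPCR runs, and want the downstream
statistics reproducible and testable rather than buried in one-off
scripts.

## What it computes

**Screening & curation.** Candidate proteins are matched against a PR
panel (internal Smith–Waterman search, or an imported DIAMOND/BLAST
tabular hit file filtered at E ≤ 10⁻⁷) and curated with two rules:
length > 100 aa, and coverage of the proton-pumping C-helix region —
the global alignment to an annotated reference must place residues at
≥ 3 of the 4 key positions 97/101/105/108.

**Residue classification.** Each curated protein is mapped onto the
reference numbering by optimal global alignment (BLOSUM62, affine gaps
11/1). The proton-pump triad call is `functional` iff positions
97/101/108 hold exactly D/T/E; the spectral tuning call at 105 is
`green` for L/M, `blue` for Q, `unknown` otherwise.

**PR OTUs.** Greedy cd-hit-style clustering at 82% identity (identity
over the shorter sequence): sequences visited longest-first, each joins
the first cluster whose representative it matches at ≥ 0.82, else
founds a new one.

**Metagenomic abundance.** With coverage C(g) = reads(g)/length(g), the
fraction of PR-bearing cells is

    f_PR = mean over h in {recA, rplB, rpoB, EF-Tu} of  C(PR) / C(h)

— each housekeeping gene occurs once per genome, so each ratio is an
independent estimate of "PR genes per genome". Per-OTU relative
abundances are coverage shares of total PR coverage.

**Transcription.** Relative expression of a gene class is its
transcript coverage divided by the mean coverage of rplB, rpoB and
EF-Tu (recA is excluded from the RNA normalizer: its expression is not
constitutive in these waters). The blue/green transcript partition
splits colored PR transcript coverage, exposing the characteristic
inversion where green genes dominate the DNA but blue variants dominate
transcription.

**qPCR.** Standard curves Cq = b + m·log₁₀(copies) over decade
dilutions (10⁸..10²), efficiency E = 10^(−1/m) − 1, copies from the
mean of triplicate Cq, and the 16S-corrected fraction

    f = (PR copies / 1 per genome) / (16S copies / 1.9 per genome).

## Worked example

```python
from rhodoquant import pr_bearing_fraction
from rhodoquant.simulate import default_community, simulate_gene_counts

spec = default_community()              # 10 taxa, 17% of cells carry PR
sample = simulate_gene_counts(spec, depth=2000.0, seed=42)
result = pr_bearing_fraction(sample.counts, "metaG")
for fam, ratio in result.per_housekeeping_ratio.items():
    print(f"PR / {fam:<6} = {ratio:.4f}")
print(f"PR-bearing fraction = {result.pr_fraction:.4f}")
```

prints

```
PR / recA   = 0.1699
PR / rplB   = 0.1699
PR / rpoB   = 0.1699
PR / EF-Tu  = 0.1699
PR-bearing fraction = 0.1699
```

i.e. each single-copy-gene ratio independently recovers the simulated
truth that 17% of cells carry a proteorhodopsin gene. The scripts in
`examples/` walk through each capability the same way (screening and
residue calls, OTU clustering, transcription and the blue/green
inversion, qPCR, and the full pipeline); `rhodoquant run --config
config.yml` drives everything from one YAML file.

## Layout

- `src/rhodoquant/` — library modules (`align`, `screen`, `annotate`,
  `cluster`, `counts`, `abundance`, `transcription`, `qpcr`,
  `simulate`, `pipeline`, `cli`)
- `examples/` — one short narrative script per capability
- `tests/` — pytest suite with independent oracles (alignment
  enumeration, brute-force clustering) and simulation-based recovery
  checks
- `docs/methods.md` — models, assumptions, parameter choices and known
  limitations
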