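# foldprep

Fast protein structure prediction lives or dies on the plumbing around the
neural network: how the multiple sequence alignment (MSA) is built and
thinned, how per-chain alignments are paired for complexes, how input
features encode chain breaks, how predictions are ranked, and how batches
are scheduled so the model is compiled as rarely as possible. `foldprep`
implements that computational layer as a tested Python library with a thin
CLI, against a pluggable predictor contract — so the algorithms can be
exercised, verified and reused at desk scale without GPUs, model weights or
database downloads.

It is intended for structural-bioinformatics developers and
methods-oriented users who need these components as importable,
deterministic pieces rather than as internals of a monolithic pipeline.

## What is implemented

- **MSA I/O** (`foldprep.msa`): A3M (lowercase-insertion convention),
  aligned FASTA, Stockholm and Clustal reading, A3M writing; sequence
  identity and coverage primitives with the query length as denominator.
- **Diversity filtering** (`foldprep.filtering`): the staged redundancy
  filters — per-cluster 95% maximum pairwise identity, a BLOSUM62
  score-per-column (qsc) filter that activates at 100 hits, and the
  identity-bucketed diversity filter that keeps the `diff = 3000` most
  diverse rows per saturated bucket ([0–0.2], (0.2–0.4], …, (0.8–1.0]),
  filtering strictly within buckets so close-homolog redundancy removal
  never costs remote-homolog diversity. Buckets under 1,000 rows pass
  through unfiltered.
- **MSA construction** (`foldprep.pipeline`): E-value acceptance (< 0.1),
  cluster expansion by composing stored member↔representative alignments
  into the query frame, the staged filters, and a two-database build; plus
  a deterministic exhaustive Smith–Waterman backend with Karlin–Altschul
  E-values as desk-scale search stand-in.
- **Complex pairing** (`foldprep.pairing`): best-hit-per-chain pairing by
  species (50% query-coverage gate, smallest E-value per chain) and
  accession-ordinal genome-distance pairing for prokaryotes.
- **Feature assembly** (`foldprep.features`): block-diagonal homo- and
  hetero-oligomer MSA layouts, residue-index chain offsets (> 32, default
  200) with clipped relative-position bins, seeded MSA subsampling (512
  cluster rows + 1,024 extras), and 10% fixed-size padding.
- **Ranking** (`foldprep.ranking`): mean pLDDT, inter-PAE, pTM and ipTM
  from the PAE matrix; single chains rank by pLDDT, complexes by
  (interface) predicted TM-score.
- **Batch scheduling** (`foldprep.scheduler`): length-sorted processing,
  compile cache keyed on (model configuration, padded shape), recycle loop
  (default 3) with tolerance- and score-based early stopping (e.g. stop at
  pLDDT ≥ 85), seed series for structure sampling, event logging.
- **Database reduction** (`foldprep.dbreduce`): assign-to-cluster at >30%
  identity / ≥90% self-coverage, greedy remainder clustering, and
  per-cluster reduction to the 10 most diverse members.
- **2D rendering** (`foldprep.render2d`): depth-ordered, depth-shaded
  segment data for the lightweight pseudo-3D backbone plot, and MSA
  coverage plot data.
- **Synthetic fixtures** (`foldprep.fixtures`): seed-deterministic
  generators for MSAs with exact identity targets, species hit layouts,
  PAE matrices, clustered databases and scripted mock predictors.

See `docs/methods.md` for the algorithms, parameter defaults and their
rationale.

## Worked example

Thin a saturated MSA with the bucketed diversity filter, then rank three
mock complex predictions:

```python
import numpy as np
from foldprep.fixtures import make_msa, make_pae
from foldprep.filtering import FilterParams, bucketed_diff_filter
from foldprep.ranking import PredictionScores, rank_predictions

msa = make_msa(12000, 50, [0.1, 0.3, 0.5, 0.7, 0.9], seed=0)
out = bucketed_diff_filter(msa, FilterParams(diff=1500))
print(f"{len(msa)} rows in -> {len(out)} rows out")

partition = [(0, 60), (60, 140)]
preds = [
    PredictionScores(plddt=np.full(140, 72.0),
                     pae=make_pae(140, partition, 3.0, 12.0, 0.5, seed=s),
                     partition=partition, name=f"model_{s+1}")
    for s in range(3)
]
for s in rank_predictions(preds, "complex"):
    print(f"{s.name}: ipTM={s.iptm:.3f}  inter-PAE={s.inter_pae:.2f} A  "
          f"mean pLDDT={s.mean_plddt:.1f}")
```

Output:

```
12001 rows in -> 7501 rows out
model_3: ipTM=0.123  inter-PAE=12.01 A  mean pLDDT=72.0
model_2: ipTM=0.122  inter-PAE=11.99 A  mean pLDDT=72.0
model_1: ipTM=0.121  inter-PAE=12.00 A  mean pLDDT=72.0
```

The 12,000 input rows sit 2,400 per identity bucket; each bucket is
reduced to its 1,500 most diverse rows, giving 5 × 1,500 + 1 = 7,501. The
three predictions tie on pLDDT, so complex mode ranks them by interface
predicted TM-score computed from the cross-chain PAE blocks (~12 Å here —
a low-confidence interface, hence ipTM ≈ 0.12).

A CLI mirrors the common operations, e.g.:

```bash
foldprep convert --in-format sto input.sto output.a3m
foldprep filter input.a3m output.a3m --diff 3000 --max-seq-id 0.95
foldprep pair --mode species chainA.tsv chainB.tsv --out paired.a3m
foldprep rank --mode complex scores/*.json
```

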