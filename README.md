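# pepgrasp

Guided assembly-based homology search over short peptide read databases.

Given a query protein and a database of short peptide reads (20–40 aa, as
produced by gene callers on ~100 bp reads), `pepgrasp` simultaneously
aligns and assembles: reduced-alphabet k-mer seeds are grown into contigs
by following pre-built *extension links* (directed maximal suffix/prefix
overlap edges between reads), re-scoring after every link traversal with a
banded affine-gap Needleman–Wunsch and pruning paths that fall a fixed
number of bits below their own best score.  Locally assembled pieces are
greedily re-merged (recalibration), scored with BLAST-style bit scores and
E-values, and finally all database reads are recruited onto the surviving
contigs by near-exact ungapped placement (≥ 60 % of the read aligned, ≤ 3
substitutions).  The union of recruited reads is the homolog read set of
the query.

The package also ships a peptide-space read simulator with exact per-read
provenance and the recall/precision/F-measure/AUC evaluation used to
benchmark this kind of search.

## Layout

| module | contents |
|---|---|
| `pepgrasp.seqcore` | alphabets, GBMR10 reduced alphabet, BLOSUM62, Karlin–Altschul bit-score/E-value statistics |
| `pepgrasp.index` | peptide database, suffix + LCP arrays, extension-link tables (fan-out ≤ 20, min overlap 10 aa), reduced k-mer seed index, versioned save/load |
| `pepgrasp.search` | seeding (6-mer, score ≥ 6·0.7·ā), banded DP (band 40), link-guided extension (depth ≤ 20/direction, 25-bit drop-off) |
| `pepgrasp.finalize` | greedy recalibration merging, ungapped post-mapping, homolog set collection |
| `pepgrasp.simdata` | DS-style simulator: coverage/length/error model, ground-truth intervals (> 60 % rule) |
| `pepgrasp.evaluate` | TP/FP/FN, recall/precision/F, ROC points over E-value cutoffs, precision-decrement AUC |
| `pepgrasp.cli` | `pepgrasp` command-line entry point and pipeline orchestration |

## CLI

```bash
# simulate a read database with provenance (or bring your own FASTA)
pepgrasp simulate --n-random 5 --coverage 10 --read-len 33 --error 0.01 \
    --seed 17 --out simdb/

# build the index once per database
pepgrasp index --db simdb/reads.faa --out idx/ --min-overlap 10 --max-links 20 --k 6

# search queries; writes contigs.faa, assignments.tsv, homologs.txt,
# run_config.json (+ metrics.json when --truth is given)
pepgrasp search --index idx/ --query simdb/sources.faa --evalue 1e-3 \
    --truth simdb/truth.json --out results/

# or everything in one go (simulates its own data when --db is omitted)
pepgrasp pipeline --seed 17 --out run/

# metrics from existing artifacts
pepgrasp evaluate --results results/ --truth simdb/truth.json --out metrics.json
```

Output files: `contigs.faa` (assembled contigs, with bit score and E-value
in the header), `assignments.tsv` (`read_id  contig_id  offset
aligned_fraction  substitutions`), `homologs.txt` (`query_id  read_id`
pairs), and `run_config.json` (full parameter fingerprint).  Identical
inputs and parameters produce byte-identical outputs regardless of
`--workers`.

## Defaults

6-mer seeds in the GBMR10 reduced alphabet with full-alphabet score
≥ 6·0.7·ā (ā = 5.8 for BLOSUM62, threshold 24.36); BLOSUM62 with gap
open/extend −11/−1; band 40; 25-bit drop-off; extension depth 20 per
direction; link fan-out 20; minimum overlap 10 aa; Karlin–Altschul
λ = 0.267, K = 0.041 (standard gapped BLOSUM62(11,1) constants).
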