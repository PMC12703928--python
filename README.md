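# bitrank

Rank-support data structures for bit vectors and strings over fixed
alphabets, with exact storage accounting.

A *rank* query on a bit vector returns the number of set bits among the
first `i` positions; on a string, the number of occurrences of a symbol
`c` among the first `i` characters (the core operation of FM-index
occurrence counting). This package implements:

* **Bit vectors with rank directories** in four layouts — single- or
  two-layer prefix-sum directories, each either conventional or
  *paired*: one directory entry per pair of blocks (and per pair of
  superblocks), halving directory storage. Queries in a pair's left
  member subtract a suffix popcount; queries in the right member add a
  prefix popcount. Block widths 64 or 512 bits, 16-bit L1 / 64-bit L0
  counters, 65,536-bit superblocks by default.
* **Two block-counting strategies** — classic *shift-and-count* and the
  branch-free *mask-and-count*, which indexes an array of `2w+1`
  precomputed masks by the offset within a block pair (implemented
  portably at the 64-bit word-group level).
* **String rank** in three structures — `mbv` (one indicator bit vector
  per symbol), `fbv` (*flattened bit vectors*: `ceil(log2 σ)` bit planes
  scattering each symbol's code bits, plus one rank directory per
  symbol; indicator words are reconstructed on the fly by ANDing planes
  or their complements), and `pfbv` (fbv with paired directories).
  Alphabets up to σ = 256.
* **Exact storage accounting** — closed-form stored-bit breakdowns
  (payload, L1, L0) that equal the measured size of real serialized
  builds, reported as overhead-% and bits/char.

## Library quick start

```python
import numpy as np
import bitrank as br

bits = br.random_bits(seed=1, n=1_000_000, density=0.5)
v = br.build(bits, br.RankConfig(block_bits=512, paired=True))
v.rank(123_456)            # scalar query
v.rank(np.arange(1000))    # vectorized queries
v.storage_bits().overhead_percent   # 1.6 at large n

s = br.StringRank.build("CAAGTACG", br.Alphabet.dna(), kind="pfbv")
s.rank(8, 1)               # occurrences of 'C' (code 1) in the prefix -> 2
```

## CLI

```sh
bitrank build genome.fa -o genome.idx --structure pfbv --block 512
bitrank rank genome.idx --pos 1000 --symbol C
bitrank space --structure pfbv --block 512 --sigma 4 --length 1000000000
bitrank space --grid bv        # overhead % of the four two-layer layouts
bitrank space --grid strings   # bits/char grid over sigma in {4,5,16,21,255}
bitrank bench genome.idx --queries 100000 --seed 1   # informational timing
```

Inputs: FASTA (`--format fasta`, DNA; `--unknown extra` maps non-ACGT
letters to a fifth symbol), raw bytes (`--format raw`, one symbol per
byte), or raw bits (`--format bits`, for `--structure bv`). Timing
output is hardware-dependent and informational only; mask and shift
strategies are cross-checked for equality while benchmarking.

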