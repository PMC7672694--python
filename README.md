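# hicorient

Probabilistic correction of contig **orientation errors** in
chromosome-length Hi-C scaffolds.

Hi-C scaffolding tools (3D-DNA and relatives) order short-read contigs
along chromosomes with high accuracy, but short contigs are frequently
placed in the wrong orientation because they have few contacts with their
neighbors. These misorientations are too small to spot in a contact-map
browser, yet they corrupt gene prediction, read alignment and synteny
analysis downstream. `hicorient` takes an existing layout (AGP or 3D-DNA
`.assembly`) plus the Hi-C read pairs (Juicer `merged_nodups.txt`, a
generic pairs dialect, or SAM/BAM), and decodes the globally most probable
orientation for every contig.

## Model

A super-scaffold is an ordered run of contigs with lengths $L_i$ and
orientations $\theta_i \in \{+,-\}$. For a contact $r = (x, y)$ between
contigs $i < j$ (offsets in each contig's native forward frame), the
implied genomic separation is fixed by the orientation pair:

$$d(r \mid \theta_i, \theta_j) = \big(\theta_i = -\,?\; x : L_i - x\big) + D + \big(\theta_j = +\,?\; y : L_j - y\big),$$

where $D = \sum_{i<s<j} L_s$ is the intervening contig length (gaps are
assumed empty). Each contact contributes $p(d)/Z_{ij}$, with $p(d)$ the
contact probability at separation $d$ and $Z_{ij}$ a normalization
integral that is *identical across the four orientation cases*, so it
cancels from every decision. $p(d)$ is estimated per dataset: kernel
density estimation on the intra-contig separations of the longest contig,
a power-law base function $p(d) = c_1 d^{-c_2}$, a cubic short-range
correction below 3 kb, and a constant tail beyond a threshold $K$ (by
default the third quantile of the separation histogram) where contacts are
effectively random.

Because $p(d)$ is constant beyond $K$, only contig pairs within $K$
intervening bp carry orientation information. The decoder builds a hidden
Markov model whose states are orientation assignments of a sliding window
of neighboring contigs — fixed arity $k$, or an adaptive arity $k(j)$ that
widens over runs of short contigs and collapses to 2 between long ones —
and finds $\arg\max_\Theta P(R,\Theta)$ exactly with the Viterbi
algorithm. Ties are broken by fewest flips relative to the input, so
contigs with no usable contacts are left untouched.

## Worked example

`examples/simulate_and_refine.py` simulates a 3 Mb chromosome tiled by
contigs (median 50 kb), 40 000 contacts with power-law separations, and
30% of input orientations flipped, then runs the full pipeline:

```
simulated 59 contigs, 15 flipped in the input
K = 12718 bp (third quantile), fitted decay exponent c2 = 1.046
refine flipped 15 contigs (mean confidence 1.000)
local error rate: 10.2% -> 0.0%
flip confusion: TP=15 FP=0 FN=0 TN=44
100.0% of the flipped contigs were restored to their true orientation
```

`K` is the automatically selected tail threshold; `c2` is the fitted decay
exponent (truth 1.0); the flip confusion counts treat each performed flip
as a positive call. The other examples show the $p(d)$ estimator in
isolation (`distance_decay.py`) and the per-pair relative orientation
probability matrix $M_{ij}$ (`confidence_matrix.py`), whose entries near 1
mean the contacts between contigs $i$ and $j$ pin down contig $i$'s
orientation.

The same workflow is available from the shell:

```bash
hicorient simulate --out sim --seed 5
hicorient refine --layout sim/scrambled_layout.agp --contacts sim/contacts.pairs --out refined
hicorient evaluate --layout refined/corrected.agp --baseline sim/scrambled_layout.agp --truth sim/truth.tsv
```

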