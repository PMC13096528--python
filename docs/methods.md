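# Methods

## The optimization procedure

`recap` searches over *generation prompts* for a black-box multimodal
model. The model is used in a describe-then-classify configuration: for an
image `x`, the generation prompt `q` elicits a description
`s = MLLM(x, q)`, and the classification prompt `p` (held fixed) elicits a
label from `[p, s]`. The search maintains a candidate pool; each iteration
it

1. collects, for every pool member, the training error set `J_error` from
   cached descriptions (classification at temperature 0.0);
2. samples `l` error subsets without replacement (subset size clamped to
   `|J_error|`; a prompt with no errors is carried forward unchanged,
   since reflecting on an empty set is undefined);
3. issues one *reflect* call per subset and one *modify* call per
   reflection, producing up to `l` revised prompts per member;
4. generates descriptions for each genuinely new prompt (write-once cache:
   exactly `|D|` describe calls per distinct prompt per run);
5. scores all candidates — survivors plus revisions — with the phase's
   scoring function and retains those at or above the `b`-th highest
   score, truncating ties toward the earliest creation index.

Candidate pools have **set semantics**: a revision whose text already
exists is the existing candidate, not a new one. This keeps the beam
heterogeneous (deterministic backends readily propose identical revisions
for identical error subsets) and makes the per-distinct-prompt call
accounting exact.

Phase 1 (diversification) scores by terminology diversity
`D(q) = T̃(q) + Ũ(q)`; phase 2 scores by training accuracy
`1 − |J_error|/|D|`, computed in exact rational arithmetic. The final
prompt `q*` is always the accuracy argmax over the final pool, regardless
of phase order, because accuracy is the deployment metric. With zero
iterations configured, `q*` is the seed prompt with its measured accuracy.

Selecting prompts by empirical training accuracy on a small set is a
noisy argmax and can favor prompts that fit observation noise; the
diversification phase counteracts this by pushing the pool toward broad,
criteria-rich prompts *before* accuracy pressure is applied. This
exploration-then-exploitation split is what the two-phase dynamics tests
exercise.

### What counts as a "biomedical term"

`T(q)` is the number of *distinct* lexicon terms matched in the prompt
(type-level, so `T` is consistent with the set-valued uniqueness `U`);
matching is case-insensitive, ASCII-folded, word-boundary based, with
multi-word terms claiming their spans before any sub-term. The lexicon is
an explicit plain-text file — the package ships a ~150-term pathology
lexicon — because no principled universal term detector exists; using an
auditable list makes `T` and `U` reproducible. Uniqueness can be scored
against the current candidate pool or against the cumulative history of
generated prompts (the default); both are legitimate readings of
"appears in no other prompt" and the trace records which was used.
Normalization maxima are taken over the pool being scored; a component
with a zero maximum contributes 0 (avoids division by zero while keeping
`D ∈ [0, 2]`).

For trajectory reporting, the trace additionally records the *raw* mean
retained term count and uniqueness per iteration. The normalized `D` is a
selection score: retention is an argmax over it, so the retained pool sits
near the normalized ceiling from the first iteration, and growth of the
diagnostic vocabulary is only visible in the unnormalized counts.

## Hyperparameters

| parameter | default | meaning |
|---|---|---|
| `beam_width` (b) | 4 | prompts retained per iteration |
| `reflections_per_prompt` (l) | 4 | error subsets / revisions per member |
| `error_subset_size` | 4 | error cases shown per reflect call (clamped) |
| `iterations_phase1` | 3 | diversification iterations |
| `iterations_phase2` | 6 | accuracy iterations (convergence plateau in practice) |
| temperatures | 0.7 / 0.0 / 0.7 / 0.7 | describe / classify / reflect / modify |
| `uniqueness_scope` | history | comparison scope for U |

All randomness flows from one root seed through named substreams
(dataset sampling, subset sampling, simulated noise), so two runs with
identical configuration produce byte-identical traces.

## The synthetic world and simulated backend

The synthetic world makes the whole pipeline testable offline. Ground
truth is a `WorldSpec`: class labels; a vocabulary `V` of candidate terms
(drawn from the pathology lexicon); an informative subset `I ⊆ V` whose
per-class Bernoulli probabilities carry the class signal (default: 6
informative terms among 60, each at probability 0.9 in the class that owns
it and 0.1 elsewhere, classes owning disjoint halves of `I`); and a report
flip-noise rate (default 0.05). Images are latent binary feature vectors
sampled class-conditionally; optional rendered thumbnails (one grayscale
motif per active feature) exercise file-based I/O paths.

The simulated backend is a pure function of (world, request, seeded
noise):

* **describe** reports `term: present/absent` for each informative term
  the prompt asks about; each report is flipped with the noise rate,
  seeded per (world, image, term). Keying the noise to the image and
  feature — rather than to the whole request — means re-asking with
  different wording does not re-roll what is visible in the image; prompt
  comparisons become paired (common random numbers), so selection cannot
  chase per-prompt noise draws, and caching/replay/order cannot change
  outcomes. Terms outside `I`, and decoy terms, are silently ignored.
* **classify** parses the reports back out of the description and returns
  the maximum-a-posteriori class under the world's true Bernoulli
  parameters with a uniform prior (first label wins exact ties); with no
  reports it draws a label uniformly (seeded), giving the chance-level
  zero-shot baseline.
* **reflect** names the informative terms absent from the subset's
  descriptions, ranked by how often the hallmark is actually present and
  characteristic of the case's true class; all terms tied at the maximal
  frequency are suggested (broad early, sharply targeted once only a few
  cases remain misclassified), ties resolved in world order.
* **modify** appends the suggested terms to the parent prompt. When the
  modification template emphasizes novel terminology (the
  diversification-phase template), the simulated model behaves like one
  told to explore: it keeps only the strongest suggestion and appends 8
  fresh random vocabulary terms instead. This split is what produces the
  observable two-phase behavior — vocabulary breadth grows during
  diversification while accuracy still has headroom, then the accuracy
  phase closes the remaining coverage gap.

The closed-form `analytic_accuracy` enumerates all report vectors over the
covered terms (noise folded into the observation distribution, the reader
using the true parameters exactly as the backend does) and is the
calibration oracle: noiseless full-coverage simulated accuracy matches it
within binomial error, and zero coverage gives `1/|labels|`.

### What the synthetic world does and does not show

The world encodes the causal premise that richer, criteria-bearing prompts
yield more diagnostic descriptions. Passing tests therefore demonstrate
the *mechanics* — error-driven refinement recovers the informative
criteria, diversity grows before accuracy, optimized descriptions separate
in embedding space — not performance on real histology. Descriptions are
structured `term: present/absent` lines, not prose; hallucination beyond
flip noise, stain variation, spatial context, and inter-observer ambiguity
are all absent. Real-image performance depends on the remote model and
dataset and must be measured through the API adapter.

## Evaluation choices

* **Confusion matrices** tally true × predicted counts with a sentinel
  column for unparseable replies; unparseable predictions count as
  misclassifications (the error set admits no abstain state).
* **Confidence intervals**: single-run accuracies use the Wilson score
  interval (well-behaved near 1.0; implemented in closed form and checked
  against an independent implementation to 1e-12); multi-run summaries use
  mean ± t·sd across runs. The report records which method was used.
* **Label parsing** is a case-insensitive word-boundary search for label
  names (longest first) plus an explicit alias table; zero or multiple
  distinct labels found means the reply is unparseable. Aliasing is
  explicit, never fuzzy.
* **Embedding separability** is the mean silhouette coefficient over the
  *full-dimensional* description embeddings; the 2-D UMAP projection
  (Euclidean metric, seeded, neighbor count configurable) is for
  visualization export only, so the separability claim does not depend on
  projection hyperparameters. The bundled embedder hashes word uni- and
  bigrams into a signed 768-dimensional space and L2-normalizes; it is
  deterministic across processes. Empty descriptions embed as flagged
  zero rows, and a set of coincident points scores 0.0 by convention
  (the silhouette is undefined there; no structure means no separation).

## Problem sizes

Tests and the acceptance script run the full default configuration
(2 classes × 30 training items, 60-term vocabulary, b = 4, l = 4, 3 + 6
iterations) across five replicate seeds, plus calibration checks at
n = 1000 (Bayes consistency) and n = 400 (chance-level fallback). A single
replicate makes roughly 10⁴ simulated backend calls. These sizes are the
package's standard demonstration conditions; the library itself has no
intrinsic size limits.

## Known limitations

* The simulated backend's reflect/modify channel is intentionally
  legible; it cannot model the failure modes of free-text reflection
  (vague diagnoses, hallucinated criteria).
* Term detection is lexicon-membership, not concept extraction; synonyms
  or paraphrases outside the lexicon are invisible to `T` and `U`.
* The remote HTTP adapter is a thin chat-completions client with bounded
  exponential-backoff retries; it is exercised only through record/replay
  transcripts in tests, never live.
* Beam retention with oldest-first tie-breaking favors established
  prompts; on plateaus where many prompts tie exactly, newer equivalent
  revisions are never adopted.
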