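# Methods

## The measurement problem

Generative models answer a document-level relation-extraction prompt with
free text that should contain a JSON object holding an `entities` section
and a `relations` section of 〈source, type, target〉 triplets.  Two models
with the same underlying extraction ability can receive very different
scores depending on how the evaluation treats (a) surface variation of
entity mentions, (b) superficial format damage, and (c) run-to-run
sampling variability.  This package separates those concerns into explicit,
individually tested stages.

## Reference construction

The gold corpus is text-bound: the same fact may be annotated several times
in one document, on different mentions of the same entities.  The
document-level reference is built per document in three steps: collect all
text-bound relations; replace each argument by its *acceptable-form set*;
remove duplicates (same type, identical source and target sets).

Acceptable-form sets are the connected components of the union of two link
relations over a document's mentions: membership in a coreference set, and
a shared entity-linking `(resource, class identifier)` pair.  Components
are computed with union–find; taking the union of both link kinds is safe
because coreferent mentions are type-homogeneous and share identifiers when
linked, so components never mix entity types.  All forms are Unicode
case-folded (full case fold, not `lower()`) and whitespace-collapsed.  The
strict variant replaces step 2 by the singleton normalized form of the
annotated argument mention; string normalization is retained in both modes,
so the strict/equivalence contrast isolates exactly the semantic-equivalence
information.

Relations whose form sets overlap without being identical remain distinct:
deduplication requires *identical* sets.  Every document-level relation
carries provenance to the text-bound relations it aggregates.

## Output repair

Repair is deliberately minimal and content-preserving, in fixed order and at
most three passes: (1) strip non-JSON framing (markdown fences, prose
before the first `{`/`[` and after the last `}`/`]`); (2) delete trailing
and duplicated commas, with a string-aware scanner so commas inside values
are untouched; (3) close unterminated strings and unmatched
brackets/braces at the end of the text.  Repair never reorders or rewrites
values.  Runs that still do not parse are `unrecoverable` and excluded from
scoring and consistency; a parseable object *without* a `relations` key is a
valid run with an empty extraction (a semantic failure, not a format one).
Relation objects missing any of the required `source`/`type`/`target` keys
are dropped with a logged warning; all repair actions are logged per run for
audit.

## Scoring

A prediction matches a reference relation iff the type label is identical
(exact comparison by default; type confusion is a real error under a strict
schema, though a case-insensitive flag exists for sensitivity analyses) and
the normalized source and target forms are members of the respective
acceptable-form sets.  TP is counted on the reference side: a reference
relation matched by several predictions contributes one TP and the surplus
matched predictions are ignored (neither TP nor FP).  One prediction may
support the TP of several distinct reference relations; this keeps
`TP + FN = |reference|` exact and TP monotone under growth of the form sets,
which in turn guarantees the equivalence-mode-dominates-strict-mode
property.  Two identical predictions matching nothing count as two FP
(predictions are not deduplicated before FP counting; this is an open
interpretive choice, surfaced here).  An empty prediction list against an
empty reference scores P = R = F1 = 1 (vacuously perfect; real documents
always carry relations, so this only affects synthetic edge cases).

## Consistency

Per (model, document), the well-formed runs are raters and every unique
predicted triplet is a subject rated present/absent per run, an N×2 matrix.
Subject identity is strict — raw strings, whitespace-trimmed, no case
folding — because the measure is meant to be computable at inference time
without the gold annotation; a normalization flag exists for sensitivity
analyses only.  Fleiss' kappa is

    P_i = [Σ_j n_ij (n_ij − 1)] / [n (n − 1)],   P̄ = mean_i P_i,
    P_e = Σ_j p_j²,   κ = (P̄ − P_e) / (1 − P_e).

Two degeneracies are intrinsic to the presence/absence construction: all
runs empty (N = 0) and all subjects present in every run (P_e = 1).  Both
mean perfect observed agreement, so κ := 1 with a `degenerate` flag.
`P_e = 1` with imperfect agreement cannot arise (absent-everywhere triplets
are never enumerated as subjects) and is asserted.  Well-formed empty runs
are raters (they rate every subject absent), not missing data.  Documents
with fewer than two well-formed runs are excluded from consistency with a
logged reason code; documents with no well-formed run are excluded from
accuracy as well.

## Covariates and correlation

Document length is the UTF-8 byte count of the text (closer to LLM token
costs than word counts); complexity is the number of entity mentions plus
text-bound relations, repetitions included.  Accuracy–consistency
association is tested at the document level, one observation per (model,
document), with Pearson, Spearman (midrank ties) and Kendall tau-b
(tie-corrected; κ and F1 tie often).  A one-sample K–S test against a
normal with sample-estimated parameters gates nothing but annotates whether
the parametric coefficient is trustworthy; with estimated parameters the
test is anti-conservative (the Lilliefors situation) and is reported as
such rather than corrected.  Raw p-values are reported without
multiple-testing correction.

## Synthetic study design

The generator's defaults emulate the reference study conditions: 165
documents, 5 runs per document (825 answers per model), roughly 10
relations per document (Poisson, minimum 1), and lexicon families of
scientific name / common name / acronym sharing a synthetic class
identifier, sized so that about three quarters of reference relations carry
a multi-form argument (the observed corpus proportion is 1244/1652 ≈ 0.75;
the default generator yields ≈ 0.74).  Document text is template prose with
exact spans — sufficient because no pipeline stage reads free text except
the byte-length covariate.  Pests, plants and vectors carry synthetic NCBI
Taxonomy identifiers, locations GeoNames identifiers; diseases are unlinked
and rely on coreference alone, mirroring the annotation practice of the
reference corpus.

Error injection follows the recoverable/disruptive taxonomy:

* `p_alt_form` — an argument is emitted with a different attested family
  form (recoverable under equivalence scoring, disruptive for strict
  scoring and for consistency);
* `p_drop`, `p_drop_hard`, `hard_fraction` — misses.  Relations are a
  difficulty mixture: a `hard_fraction` churn with per-run drop probability
  `p_drop_hard`, the rest are stable at `p_drop`.  Uniform i.i.d. drops
  would give chance-level kappa for every document regardless of the rate
  (chance-corrected agreement of independent raters is ≈ 0), which cannot
  reproduce the clearly positive kappas real models show; the mixture of
  stable and churning relations is what creates between-subject variance
  and hence positive kappa;
* `drop_persistence` — probability a miss repeats identically across all
  runs of a document.  Low-temperature models fail the *same* relations
  run after run; persistent misses lower accuracy without lowering kappa
  (a never-emitted triplet is not a subject).  Default 0.7;
* `alt_form_persistence` — probability the form choice for an argument is a
  stable per-document preference rather than a fresh per-run draw.  A
  stable non-annotated preference lowers strict accuracy persistently
  without hurting consistency.  Default 0.7;
* `p_type_confusion` — the relation type is swapped for another label
  (e.g. the disease used in place of the pathogen), always an error;
* `p_hallucinate` — Poisson-many spurious triplets per run, drawn from a
  reserved out-of-lexicon vocabulary so they can never match a reference;
* `p_trailing_comma`, `p_fence`, `p_missing_key` — recoverable format
  corruptions; `p_truncate` — a garbled premature termination constructed
  to defeat superficial repair (it embeds a missing-property-name fragment
  before the final closing brace), hence always unrecoverable.

Default rates (`p_drop=0.03`, `p_drop_hard=0.65`, `hard_fraction=0.7`,
`p_alt_form=0.3`, `p_type_confusion=0.05`, `p_hallucinate=0.8`, format
corruption rates of a few percent or less) were chosen once so that the
default ensemble lands in the realistic mid range observed for current
models on this task — macro accuracy ≈ 0.6 with equivalence, ≈ 0.44 strict,
macro kappa ≈ 0.27, ≈ 6% recoverable and ≈ 0% unrecoverable format errors.

Two latent mechanisms control the accuracy–consistency dependence
structure.  `latent_coupling` ties the per-document hard fraction and
hallucination rate to a shared per-document difficulty latent (uniform on
[0, 1]), degrading accuracy and consistency together — the coupled
construction.  The decoupled construction instead drives accuracy through
fully persistent drops (invisible to kappa) and consistency through
per-run surface churn (invisible to equivalence accuracy), from independent
latents, so the true document-level association is zero by construction.

## Problem sizes of the verification checks

The oracle and recovery checks run at: 1000 random rating matrices
(N ≤ 50, n ∈ 2..10) against an independently coded kappa formula
(agreement to 1e−12); 500 random prediction/reference instances against a
brute-force pairwise matcher; 200 documents for the equivalence-dominance
check (`p_alt_form = 0.5`); 40 documents for the noise-free oracle (exact
macro accuracy and consistency of 1); 100 documents × 5 runs × 10 relations
for rate recovery (`p_drop = 0.2`, `p_hallucinate = 1.0`, both within 3 SE);
and 150 documents each for the coupled (positive Spearman, p < 0.05) and
decoupled (inside the 95% null band ±1.96/√(n−1)) correlation checks.

## What the synthetic study does and does not show

Passing these checks demonstrates that the measurement chain is correct:
aggregation, repair, matching, kappa and the correlation machinery do what
they claim on data whose ground truth is known.  It does not validate the
generator as a model of any particular LLM: real generations have richer
failure modes (paraphrased arguments outside the annotated form sets,
boundary variations, nested/discontinuous mention effects, prompt
sensitivity), real corpora have heavier-tailed document lengths, and the
generator's difficulty latent is a one-dimensional abstraction.  Synthetic
accuracy/consistency levels and their correlation are consequences of the
configured rates, not predictions about any model.

## Known limitations

* The corpus readers cover the canonical JSON dialect and a
  BioNLP-ST-like standoff; other distributions must be converted.
* The generator emits single-span mentions only; discontinuous mentions are
  supported (and tested) in the corpus model but not synthesized.
* Corpus-level reference counts depend on which splits are supplied;
  `count_reference` takes whatever document collection it is given.
* The K–S normality check is anti-conservative with estimated parameters;
  it is annotated, not corrected.
* Consistency is surface-strict by design; semantically equivalent but
  differently worded triplets lower kappa.
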