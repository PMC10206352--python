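# citylisten

City-level social listening for public-health communication. `citylisten`
turns a stream of short, geo-tagged, keyword-collected posts (tweets about
COVID and vaccines, for example) into the quantities a health-communication
analyst actually reads: coherent topics with ranked key terms, an exclusive
topic assignment for every post, a four-way emotion label (joy, optimism,
sadness, anger), and per-city monthly trend tables of counts and
percentages. It is aimed at infodemiology researchers and practitioners who
want a reproducible, scriptable version of this analysis, plus a synthetic
corpus generator with known ground truth so every stage can be validated
without access to platform data.

## The method

1. **Collection & cleaning.** Keep records matching query keywords
   (case-insensitive substring) within a great-circle radius (default 20
   statute miles) of each city point. Lowercase, strip URLs and special
   characters, remove stopwords, drop documents left with fewer than three
   tokens.
2. **Topic model.** Latent Dirichlet allocation fit by collapsed Gibbs
   sampling. With θ_d the per-document topic mixture and φ_t the per-topic
   word distribution integrated out, each token's topic label is resampled
   from

       p(z = t | rest) ∝ (n_dt + α) (n_tw + β) / (n_t + V β)

   and φ̂, θ̂ are posterior means averaged over thinned post-burn-in sweeps.
3. **Choosing k.** Candidate topic counts are scored by C_V-style coherence:
   NPMI co-occurrence vectors of each topic's top words (boolean sliding
   windows, width 110), compared by cosine similarity against the topic's
   set vector, averaged. The argmax k is selected; topics whose token share
   falls below a threshold (default 5%) are flagged for pruning.
4. **Term ranking.** Topic terms are ordered by relevance
   r(w, t) = λ log φ_tw + (1 − λ) log(φ_tw / p_w), default λ = 0.6.
5. **Exclusive assignment.** Each document's θ̂_d is fused with a sentence
   embedding (a deterministic hashed random projection by default; a
   transformer encoder plugs in behind the same contract), compressed
   through a single-hidden-layer autoencoder, and K-Means with the same k
   clusters the latent codes. A Hungarian alignment maps clusters back to
   topics.
6. **Emotion & trends.** A multinomial naive-count lexicon baseline (or an
   external classifier behind the same contract) assigns one of four
   emotion labels; documents are then aggregated into (city, period,
   category) count/percentage tables with simple local-maximum peak
   detection on monthly volumes.

## Worked example

Generate a synthetic 4-topic, 2000-tweet corpus over four US cities and 18
months, then run every stage:

```sh
cat > sim_config.json <<'JSON'
{"k_true": 4, "V": 500, "D": 2000, "alpha": 0.1,
 "noise_rate": 0.05, "marker_rate": 0.1, "seed": 7}
JSON
citylisten simulate --config sim_config.json --out sim
citylisten preprocess --input sim/records.jsonl \
    --keywords covid,coronavirus --extra-stopwords covid,coronavirus --out corpus
citylisten select-k --corpus corpus --k-grid 2:8 --seed 7 --out selectk
citylisten fit --corpus corpus --k 4 --iters 1000 --burn-in 500 --seed 7 --out model
citylisten rank-terms --model model --corpus corpus --lambda 0.6 --top-n 5 --out terms.tsv
citylisten cluster --model model --corpus corpus --seed 7 --out clusters
citylisten emotions --corpus corpus --train train.tsv --out emotions.tsv
citylisten trends --corpus corpus --topics clusters/labels.tsv \
    --emotions emotions.tsv --dimension emotion --granularity month --out trends
```

The stages print:

```
wrote 2000 records to sim
kept 1996/2000 docs (loss 0.0020)
selected k=4
fitted k=4 on 1996 docs; final logL -117666.0
clustered 1996 docs into 4 topic-clusters
labeled 1996 docs
wrote 288 trend rows
```

`selected k=4` is the coherence argmax over the candidate grid
(`selectk/coherence.tsv` holds the full table — here coherence peaks at
0.895 for k = 4); the loss line says 4 of 2000 raw tweets were discarded as
too short after cleaning (0.2%). The trend table is tidy, one row per
(city, month, emotion):

```
city         period   dimension  category  count  pct
Kansas City  2020-01  emotion    anger     2      40.0
Kansas City  2020-01  emotion    joy       2      40.0
Kansas City  2020-01  emotion    optimism  0      0.0
Kansas City  2020-01  emotion    sadness   1      20.0
```

Percentages sum to 100 within each (city, month) group. Comparing the
cluster output with the generator's ground truth on this corpus gives an
adjusted Rand index of 0.80, and the emotion baseline agrees with the
generating labels on 80% of documents at a 10% marker-salting rate.

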