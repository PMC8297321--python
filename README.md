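# driftlex

Dynamic lexicon-based sentiment tracking for keyword-filtered tweet streams.

The pipeline takes a JSON-lines tweet stream (id, ISO-8601 timestamp, text,
country code) and a seed polarity lexicon (TSV of `lemma<TAB>polarity`,
polarities in [-1, 1]) and:

1. **filters** the stream with three staged keyword rule sets
   (pandemic context → topic → country), reporting a topic-by-country
   counts table;
2. **preprocesses** retained tweets (URL/mention/hashtag/emoji removal,
   letter-only tokenization, a download-free Spanish suffix lemmatizer,
   stopword removal — taggers/lemmatizers are injectable);
3. **scores** each tweet as the mean lexicon polarity over matched lemma
   occurrences and evolves per-word sentiment day by day with exponential
   smoothing `s ← (1-α)·s + α·m(d)`, learning words not yet in the lexicon
   from the tweets they ride in;
4. **archives** every per-word daily update (country, lemma, day,
   polarity, daily mean, daily count) in an append-only CSV-backed store;
5. **visualizes** results as per-word sentiment trend series and
   similarity-laid-out word clouds (PPMI + cosine similarity, classical MDS
   layout; colour = polarity, size = frequency, distance = relatedness);
6. **simulates** multi-day, multi-country streams with planted word-sentiment
   trajectories (constant / linear drift / step) so the whole pipeline is
   testable offline, plus recovery metrics (Pearson r, RMSE) between planted
   and recovered trajectories.

## CLI

One subcommand per stage plus an end-to-end runner:

```bash
driftlex synth --seed 42 --out stream.jsonl --truth truth.csv --lexicon-out lex.tsv
driftlex filter --input stream.jsonl --out retained.jsonl --counts counts.csv
driftlex run --input retained.jsonl --lexicon lex.tsv --alpha 0.3 \
             --archive-out archive.csv --lexicon-out lex_final.tsv
driftlex trends --archive archive.csv --words vacuna,pandemia --out trends.csv --plot trends.png
driftlex cloud --archive archive.csv --input retained.jsonl --words vacuna,pandemia,cura \
               --start 2021-03-01 --end 2021-03-31 --out snap.json --image snap.png
driftlex freqcloud --input retained.jsonl --out freq.csv --image freq.png
driftlex report --counts counts.csv
driftlex all --config pipeline.yaml
```

`driftlex all` reads a YAML config (input/lexicon/rules paths, engine
parameters, trend words, snapshot words + windows) and writes the retained
stream, counts CSV, archive CSV, per-partition final lexicons, trend CSVs,
snapshot JSONs and a manifest; artifacts are byte-deterministic for a fixed
config and input.  Default rule sets and a Spanish stopword list ship in
`src/driftlex/data/`.

## Layout

```
src/driftlex/
  lexicon.py     term normalization, seed lexicon TSV I/O, mutable store
  preprocess.py  cleaning, tokenization, lemmatization, stopwords, JSONL I/O
  filtering.py   keyword rule sets, three-stage filter, counts table
  engine.py      tweet scoring, daily smoothing updates, word learning
  archive.py     per-word daily history store + CSV round-trip
  viz.py         co-occurrence, PPMI/cosine, MDS layout, clouds, trends
  synth.py       planted-trajectory stream generator + recovery metrics
  cli.py         click CLI and end-to-end pipeline orchestration
```
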