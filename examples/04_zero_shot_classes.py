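"""Zero-shot product-class prediction by masking the class-token slot.

No classifier is trained: a MASK token is prepended to a BGC's domain chain
and the model's softmax at that position, restricted to class tokens, is
the prediction. Predictions from independently seeded models ensemble by
arithmetic mean, and pretraining classes can be projected onto a coarser
evaluation taxonomy via a mapping table. Runs in about a minute.
"""

import numpy as np

import bgclm as bg

spec = bg.SynthSpec(seed=0)
corpus = bg.make_corpus(spec, 600, seed=1)
train, val, test = bg.split_corpus(corpus, bg.SplitSpec((0.8, 0.1, 0.1), seed=2))
vocab = corpus.vocab

models = []
for seed in (3, 13):
    m = bg.build_random_model(
        bg.ModelConfig(vocab_size=len(vocab), hidden_dim=64, embed_dim=64,
                       n_layers=8, max_dilation=16, seed=seed), vocab)
    bg.pretrain(train, val, m,
                bg.TrainConfig(batch_size=64, learning_rate=1e-3,
                               n_epochs=10, seed=seed + 1))
    models.append(m)

def top1(predict):
    hits = sum(vocab.class_tokens[int(np.argmax(predict(r)))] == r.class_label
               for r in test)
    return hits / len(test)

for i, m in enumerate(models):
    print(f"model {i}: held-out top-1 class accuracy "
          f"{top1(lambda r, m=m: bg.predict_class(m, r.domains)):.3f}")
print("ensemble:", f"{top1(lambda r: bg.ensemble([bg.predict_class(m, r.domains) for m in models])):.3f}",
      "(arithmetic mean of the class simplexes)")

# project the 5 pretraining classes onto a 3-class evaluation taxonomy
mapping = {"class01": "polyketide", "class02": "polyketide",
           "class03": "NRP", "class04": "NRP"}  # class05 falls into "other"
eval_classes = ["polyketide", "NRP", "other"]
rec = test.records[0]
pred = bg.ensemble([bg.predict_class(m, rec.domains) for m in models])
mapped = bg.map_classes(pred, vocab.class_tokens, mapping, eval_classes)
print(f"record {rec.record_id} (true class {rec.class_label}) mapped prediction:",
      {c: round(float(p), 3) for c, p in zip(eval_classes, mapped)})
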