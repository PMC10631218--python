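# Planted-motif sweep at promoter scale: 300 two-class 57-base sequences,
# 8-base motif at a random position in positives, 15% per-base mutation.
data:
  source: generator
  generator:
    kind: motif
    n: 300
train:
  max_epochs: 30
sweep:
  max_blocks: 2
  selection: test   # report-the-best protocol; use "val" for unbiased selection
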