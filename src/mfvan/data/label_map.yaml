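# Per-dataset emotion label vocabularies and their 3-class projection
# (negative / positive / surprise).  Labels absent from a dataset's table
# are rejected; callers must filter unmappable labels (e.g. "others")
# explicitly before a 3-class run.
smic:
  negative: negative
  positive: positive
  surprise: surprise
casme2:
  happiness: positive
  surprise: surprise
  disgust: negative
  repression: negative
  sadness: negative
  fear: negative
samm:
  happiness: positive
  surprise: surprise
  anger: negative
  contempt: negative
  disgust: negative
  fear: negative
  sadness: negative
synthetic:
  negative: negative
  positive: positive
  surprise: surprise
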