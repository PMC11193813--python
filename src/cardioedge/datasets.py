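"""Reference composition of the public arrhythmia corpora.

Number of labeled 30-second samples per rhythm that the strict
label-conflict rules yield from each public source database, kept here as
the reference class-imbalance context (AFL is rare — about 0.6% of the
corpus — which is why evaluation leans on F1 rather than accuracy).
"""

NSR = "NSR"
AFIB = "AFIB"
AFL = "AFL"

#: per-database sample counts {database: {rhythm: n_30s_samples}}
REFERENCE_CORPUS_COMPOSITION = {
    "MITDB": {NSR: 602, AFIB: 102, AFL: 22},
    "AFDB": {NSR: 1275, AFIB: 1337, AFL: 343},
    "NSRDB": {NSR: 51840, AFIB: 0, AFL: 0},
    "LTAFDB": {NSR: 22834, AFIB: 7358, AFL: 0},
    "Chapman-Shaoxing": {NSR: 608, AFIB: 593, AFL: 148},
    "CPSC2018": {NSR: 918, AFIB: 1098, AFL: 0},
}

#: corpus-wide totals per rhythm
REFERENCE_CORPUS_TOTALS = {NSR: 78083, AFIB: 10488, AFL: 513}

#: native sampling rates of the source databases, Hz
DATABASE_SAMPLING_RATES = {
    "MITDB": 360.0,
    "AFDB": 250.0,
    "NSRDB": 128.0,
    "LTAFDB": 128.0,
    "Chapman-Shaoxing": 500.0,
    "CPSC2018": 500.0,
}
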