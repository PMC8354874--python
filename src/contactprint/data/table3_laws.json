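{
  "flat": {
    "0": {
      "a": 2.685,
      "b": 7.782,
      "r2": 0.837
    },
    "30": {
      "a": 3.036,
      "b": 3.465,
      "r2": 0.845
    },
    "45": {
      "a": 3.689,
      "b": 2.952,
      "r2": 0.867
    },
    "60": {
      "a": 2.807,
      "b": 3.137,
      "r2": 0.984
    },
    "90": {
      "a": 2.693,
      "b": 0.892,
      "r2": 0.893
    }
  },
  "round": {
    "0": {
      "a": 2.837,
      "b": 4.251,
      "r2": 0.974
    },
    "30": {
      "a": 3.903,
      "b": 2.89,
      "r2": 0.961
    },
    "45": {
      "a": 3.429,
      "b": 0.012,
      "r2": 0.926
    },
    "60": {
      "a": 3.062,
      "b": 1.363,
      "r2": 0.936
    },
    "90": {
      "a": 2.341,
      "b": 2.709,
      "r2": 0.953
    }
  }
}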