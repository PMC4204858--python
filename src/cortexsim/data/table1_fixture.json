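{
  "description": "Expected outcome of the 16 (movement, conversion) rule pairs for each genotype. must_succeed: the pair reproduces the genotype's layering phenotype; must_fail: it does not; either: the published mark is ambiguous and both outcomes are allowed.",
  "expected_phenotype": {
    "wild_type": "inside_out",
    "reeler": "outside_in",
    "dab1": "outside_in",
    "dab1_conditional": "conditional_misplaced"
  },
  "cells": {
    "a,i":   {"wild_type": "must_fail",    "reeler": "must_succeed", "dab1": "must_fail",    "dab1_conditional": "must_fail"},
    "b,i":   {"wild_type": "must_succeed", "reeler": "must_succeed", "dab1": "must_succeed", "dab1_conditional": "must_fail"},
    "c,i":   {"wild_type": "must_succeed", "reeler": "must_succeed", "dab1": "must_succeed", "dab1_conditional": "must_fail"},
    "d,i":   {"wild_type": "must_fail",    "reeler": "must_succeed", "dab1": "must_fail",    "dab1_conditional": "either"},
    "a,ii":  {"wild_type": "either",       "reeler": "must_succeed", "dab1": "must_fail",    "dab1_conditional": "must_succeed"},
    "b,ii":  {"wild_type": "must_succeed", "reeler": "must_succeed", "dab1": "must_succeed", "dab1_conditional": "must_succeed"},
    "c,ii":  {"wild_type": "must_succeed", "reeler": "must_succeed", "dab1": "must_succeed", "dab1_conditional": "must_succeed"},
    "d,ii":  {"wild_type": "must_fail",    "reeler": "must_succeed", "dab1": "must_fail",    "dab1_conditional": "must_succeed"},
    "a,iii": {"wild_type": "must_succeed", "reeler": "must_fail",    "dab1": "must_fail",    "dab1_conditional": "must_fail"},
    "b,iii": {"wild_type": "must_succeed", "reeler": "must_fail",    "dab1": "must_fail",    "dab1_conditional": "must_fail"},
    "c,iii": {"wild_type": "must_succeed", "reeler": "must_fail",    "dab1": "must_fail",    "dab1_conditional": "must_fail"},
    "d,iii": {"wild_type": "must_succeed", "reeler": "must_fail",    "dab1": "must_fail",    "dab1_conditional": "must_fail"},
    "a,iv":  {"wild_type": "must_succeed", "reeler": "must_succeed", "dab1": "must_fail",    "dab1_conditional": "must_fail"},
    "b,iv":  {"wild_type": "must_succeed", "reeler": "must_succeed", "dab1": "must_succeed", "dab1_conditional": "must_fail"},
    "c,iv":  {"wild_type": "must_succeed", "reeler": "must_succeed", "dab1": "must_succeed", "dab1_conditional": "must_fail"},
    "d,iv":  {"wild_type": "must_succeed", "reeler": "must_succeed", "dab1": "must_fail",    "dab1_conditional": "must_succeed"}
  }
}
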