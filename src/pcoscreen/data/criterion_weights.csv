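criterion_id,weight
C11,0.074
C12,0.074
C13,0.074
C14,0.074
C15,0.038
C16,0.068
C17,0.036
C18,0.036
C19,0.036
C110,0.023
C111,0.023
C21,0.045
C22,0.045
C23,0.045
C24,0.023
C25,0.029
C26,0.04
C27,0.021
C28,0.012
C29,0.012
C210,0.012
C31,0.017
C32,0.017
C33,0.017
C34,0.017
C35,0.017
C41,0.019
C42,0.019
C43,0.014
C44,0.014
C45,0.006
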