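channel,alternative,criterion,d_star,d_minus
physical,P1,C11,2.35,8.3
physical,P1,C12,2.35,8.3
physical,P1,C13,3.34,7.72
physical,P1,C14,2.35,8.3
physical,P1,C15,2.95,5.94
physical,P1,C16,4.24,7.17
physical,P1,C17,2.95,5.94
physical,P1,C18,2.3,4.91
physical,P1,C19,2.3,4.91
physical,P1,C110,3.1,2.72
physical,P1,C111,3.1,2.72
physical,P2,C11,9.38,1.15
physical,P2,C12,9.38,1.15
physical,P2,C13,8.54,2.37
physical,P2,C14,9.38,1.15
physical,P2,C15,6.6,2.02
physical,P2,C16,8.27,2.5
physical,P2,C17,6.6,2.02
physical,P2,C18,5.4,1.57
physical,P2,C19,5.4,1.57
physical,P2,C110,4.08,1.73
physical,P2,C111,4.08,1.73
physical,P3,C11,4.8,5.96
physical,P3,C12,4.8,5.96
physical,P3,C13,6.43,4.22
physical,P3,C14,4.97,5.79
physical,P3,C15,4.08,4.57
physical,P3,C16,5.46,5.55
physical,P3,C17,4.08,4.57
physical,P3,C18,3.38,4.34
physical,P3,C19,3.38,4.34
physical,P3,C110,2.42,3.6
physical,P3,C111,2.42,3.6
mental,M1,C21,2.35,8.3
mental,M1,C22,3.33,7.73
mental,M1,C23,3.33,7.73
mental,M1,C24,2.09,6.5
mental,M1,C25,3.34,7.72
mental,M1,C26,3.33,7.73
mental,M1,C27,2.84,6.07
mental,M1,C28,2.09,6.5
mental,M1,C29,3.24,5.78
mental,M1,C210,3.07,5.96
mental,M1,C31,2.84,6.07
mental,M1,C32,2.84,6.07
mental,M1,C33,2.84,6.07
mental,M1,C34,2.84,6.07
mental,M1,C35,2.84,6.07
mental,M1,C41,2.84,7.55
mental,M1,C42,3.49,7.55
mental,M1,C43,3.22,5.88
mental,M1,C44,2.6,4.31
mental,M1,C45,2.82,1.23
mental,M2,C21,9.38,1.15
mental,M2,C22,9.38,1.15
mental,M2,C23,9.38,1.15
mental,M2,C24,7.5,0.92
mental,M2,C25,8.54,2.37
mental,M2,C26,9.38,1.15
mental,M2,C27,6.84,1.89
mental,M2,C28,7.5,0.92
mental,M2,C29,7.5,0.92
mental,M2,C210,7.5,0.92
mental,M2,C31,6.84,1.89
mental,M2,C32,6.84,1.89
mental,M2,C33,6.84,1.89
mental,M2,C34,6.84,1.89
mental,M2,C35,6.84,1.89
mental,M2,C41,8.54,2.37
mental,M2,C42,8.54,2.37
mental,M2,C43,6.3,2.52
mental,M2,C44,4.75,1.88
mental,M2,C45,1.89,2.4
mental,M3,C21,4.8,5.96
mental,M3,C22,5.3,5.7
mental,M3,C23,5.3,5.7
mental,M3,C24,3.95,4.7
mental,M3,C25,4.97,5.79
mental,M3,C26,5.3,5.7
mental,M3,C27,4.08,4.57
mental,M3,C28,3.95,4.7
mental,M3,C29,4.59,4.33
mental,M3,C210,4.46,4.45
mental,M3,C31,3.95,4.7
mental,M3,C32,3.95,4.7
mental,M3,C33,3.95,4.7
mental,M3,C34,3.95,4.7
mental,M3,C35,3.95,4.7
mental,M3,C41,4.8,5.96
mental,M3,C42,4.8,5.96
mental,M3,C43,3.38,5.71
mental,M3,C44,2.71,4.19
mental,M3,C45,2.76,1.26
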