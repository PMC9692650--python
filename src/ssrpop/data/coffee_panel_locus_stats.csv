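locus,na,i,ho,he,f
CaEST-010,2,0.413,0.289,0.247,-0.169
SSR-08,3,0.987,0.5,0.588,0.15
SSR-30,4,0.45,0.211,0.196,-0.076
SSR-34,2,0.474,0.273,0.298,0.083
SSR-35,2,0.65,0.024,0.457,0.947
SSR-37,3,0.625,0.394,0.363,-0.085
SSR-43,2,0.625,0.636,0.434,-0.467
SSR-46,5,0.882,0.512,0.487,-0.05
SSR-48,4,0.869,0.571,0.477,-0.198
SSR-49,3,0.516,0.2,0.284,0.296
SSR-55,3,0.184,0.075,0.073,-0.03
SSR-59,2,0.264,0.148,0.137,-0.08
SSR-70,2,0.528,0.395,0.344,-0.148
SSR-71,2,0.253,0.14,0.13,-0.075
SSR-74,3,1.003,1,0.609,-0.643
SSR-84,4,1.038,0.432,0.553,0.219
SSR-87,3,0.482,0.25,0.257,0.029
SSR-100,5,0.462,0.093,0.195,0.522
SSR-106,2,0.611,0.6,0.42,-0.429
SSR-114,3,0.333,0.178,0.164,-0.086
SSR-119,2,0.619,0.619,0.427,-0.448
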