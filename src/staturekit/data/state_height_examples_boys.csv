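id,current_age,current_height,target_age,target_height,predicted_height,reported_deviation
1,11.5,146.1,12.5,149.9,151.50,1.61
2,11.5,148,12.5,155.1,155.62,0.52
3,10.7,140,11.7,145,145.78,0.79
4,10.9,149.4,11.9,158.7,156.81,-1.88
5,11,148.8,12,155.2,155.32,0.12
6,11.6,151.8,12.6,157.7,158.02,0.32
7,10.9,146.5,11.9,154.8,153.93,-0.87
8,11.4,153.7,12.4,162.5,161.64,-0.86
9,11.5,146.7,12.5,154.2,153.86,-0.34
10,11.1,147.5,12.1,156.7,155.47,-1.22
11,10.6,141.1,11.6,146.6,146.90,0.31
12,10.7,144.3,11.7,151.1,151.96,0.87
13,10.8,146.9,11.8,156.5,154.43,-2.07
14,10.9,144.1,11.9,149.3,149.37,0.07
15,10.9,153.7,11.9,162.1,159.95,-2.15
16,11,150.3,12,160.2,157.89,-2.30
17,11,135.9,12,141.8,141.25,-0.55
18,11.1,157.9,12.1,164.8,166.02,1.22
19,11.3,141.7,12.3,146.7,147.33,0.63
20,11.3,138.6,12.3,147,145.01,-1.98
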