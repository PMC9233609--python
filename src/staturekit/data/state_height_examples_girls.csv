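id,current_age,current_height,target_age,target_height,predicted_height,reported_deviation
1,10.8,146.5,11.8,154.5,151.32,-3.17
2,11.4,146.7,12.4,154.8,151.97,-2.82
3,10.9,139.1,11.9,146.3,144.41,-1.88
4,10.7,149.1,11.7,155.7,154.31,-1.38
5,10.9,158.6,11.9,162.4,163.16,0.76
6,10.9,130.8,11.9,136.5,138.34,1.84
7,11,151.2,12,157.9,156.77,-1.12
8,11,148.4,12,155.6,153.55,-2.04
9,11,146.6,12,154.7,151.99,-2.70
10,11,149.6,12,156.3,154.80,-1.49
11,11.1,157.5,12.1,161.7,162.51,0.81
12,11.1,143.4,12.1,151.3,149.22,-2.07
13,11.2,153.2,12.2,158.1,158.44,0.34
14,11.2,156.8,12.2,160.5,160.49,-0.01
15,11.5,165.4,12.5,168.3,169.89,1.59
16,11.6,139.9,12.6,148.6,145.16,-3.43
17,11.7,158.4,12.7,161.4,161.38,-0.01
18,11.5,146.4,12.5,149.9,151.96,2.06
19,10.9,150.4,11.9,159.4,155.75,-3.64
20,10.8,141.1,11.8,149,147.11,-1.88
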