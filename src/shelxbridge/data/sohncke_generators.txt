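# Hermann-Mauguin symbol | LATT centering code | generator triplets (semicolon-separated) | order of the quotient group
P 1|1||1
P 1 2 1|1|-x,y,-z|2
P 1 21 1|1|-x,y+1/2,-z|2
C 1 2 1|7|-x,y,-z|2
P 2 2 2|1|-x,-y,z;x,-y,-z|4
P 2 2 21|1|-x,-y,z+1/2;x,-y,-z|4
P 21 21 2|1|-x,-y,z;x+1/2,-y+1/2,-z|4
P 21 21 21|1|-x+1/2,-y,z+1/2;x+1/2,-y+1/2,-z|4
C 2 2 21|7|-x,-y,z+1/2;x,-y,-z|4
C 2 2 2|7|-x,-y,z;x,-y,-z|4
F 2 2 2|4|-x,-y,z;x,-y,-z|4
I 2 2 2|2|-x,-y,z;x,-y,-z|4
I 21 21 21|2|-x,-y+1/2,z;x,-y,-z+1/2|4
P 4|1|-y,x,z|4
P 41|1|-y,x,z+1/4|4
P 42|1|-y,x,z+1/2|4
P 43|1|-y,x,z+3/4|4
I 4|2|-y,x,z|4
I 41|2|-y,x+1/2,z+1/4|4
P 4 2 2|1|-y,x,z;x,-y,-z|8
P 4 21 2|1|-y+1/2,x+1/2,z;x+1/2,-y+1/2,-z|8
P 41 2 2|1|-y,x,z+1/4;x,-y,-z+1/2|8
P 41 21 2|1|-y+1/2,x+1/2,z+1/4;x+1/2,-y+1/2,-z+3/4|8
P 42 2 2|1|-y,x,z+1/2;x,-y,-z|8
P 42 21 2|1|-y+1/2,x+1/2,z+1/2;x+1/2,-y+1/2,-z+1/2|8
P 43 2 2|1|-y,x,z+3/4;x,-y,-z+1/2|8
P 43 21 2|1|-y+1/2,x+1/2,z+3/4;x+1/2,-y+1/2,-z+1/4|8
I 4 2 2|2|-y,x,z;x,-y,-z|8
I 41 2 2|2|-y,x+1/2,z+1/4;x,-y+1/2,-z+1/4|8
P 3|1|-y,x-y,z|3
P 31|1|-y,x-y,z+1/3|3
P 32|1|-y,x-y,z+2/3|3
R 3|3|-y,x-y,z|3
P 3 1 2|1|-y,x-y,z;-y,-x,-z|6
P 3 2 1|1|-y,x-y,z;y,x,-z|6
P 31 1 2|1|-y,x-y,z+1/3;-y,-x,-z+2/3|6
P 31 2 1|1|-y,x-y,z+1/3;y,x,-z|6
P 32 1 2|1|-y,x-y,z+2/3;-y,-x,-z+1/3|6
P 32 2 1|1|-y,x-y,z+2/3;y,x,-z|6
R 3 2|3|-y,x-y,z;y,x,-z|6
P 6|1|x-y,x,z|6
P 61|1|x-y,x,z+1/6|6
P 65|1|x-y,x,z+5/6|6
P 62|1|x-y,x,z+1/3|6
P 64|1|x-y,x,z+2/3|6
P 63|1|x-y,x,z+1/2|6
P 6 2 2|1|x-y,x,z;-y,-x,-z|12
P 61 2 2|1|x-y,x,z+1/6;-y,-x,-z+5/6|12
P 65 2 2|1|x-y,x,z+5/6;-y,-x,-z+1/6|12
P 62 2 2|1|x-y,x,z+1/3;-y,-x,-z+2/3|12
P 64 2 2|1|x-y,x,z+2/3;-y,-x,-z+1/3|12
P 63 2 2|1|x-y,x,z+1/2;-y,-x,-z+1/2|12
P 2 3|1|-x,-y,z;x,-y,-z;z,x,y|12
F 2 3|4|-x,-y,z;x,-y,-z;z,x,y|12
I 2 3|2|-x,-y,z;x,-y,-z;z,x,y|12
P 21 3|1|-x+1/2,-y,z+1/2;x+1/2,-y+1/2,-z;z,x,y|12
I 21 3|2|-x,-y+1/2,z;x,-y,-z+1/2;z,x,y|12
P 4 3 2|1|-y,x,z;x,-y,-z;z,x,y|24
P 42 3 2|1|-y+1/2,x+1/2,z+1/2;x,-y,-z;z,x,y|24
F 4 3 2|4|-y,x,z;x,-y,-z;z,x,y|24
F 41 3 2|4|-y+1/4,x+1/4,z+1/4;x,-y,-z;z,x,y|24
I 4 3 2|2|-y,x,z;x,-y,-z;z,x,y|24
P 43 3 2|1|-y+3/4,x+1/4,z+3/4;x+1/2,-y+1/2,-z;z,x,y|24
P 41 3 2|1|-y+1/4,x+3/4,z+1/4;x+1/2,-y+1/2,-z;z,x,y|24
I 41 3 2|2|-y+1/4,x+3/4,z+1/4;x,-y,-z+1/2;z,x,y|24
R 3:R|1|z,x,y|3
R 3 2:R|1|z,x,y;-y,-x,-z|6
P 1 1 2|1|-x,-y,z|2
P 1 1 21|1|-x,-y,z+1/2|2
B 1 1 2|6|-x,-y,z|2
A 1 2 1|5|-x,y,-z|2
I 1 2 1|2|-x,y,-z|2
I 1 21 1|2|-x,y+1/2,-z|2
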