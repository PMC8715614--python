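item,name,scale_min,scale_max,reverse,composite,excluded
1,disorganized,1,5,True,dependable,False
2,conscientious,1,5,False,dependable,True
3,undependable,1,5,True,dependable,False
4,thorough,1,5,False,dependable,False
5,agreeable,1,5,False,agreeable,False
6,difficult,1,5,True,agreeable,False
7,stubborn,1,5,True,agreeable,False
8,trustful,1,5,False,agreeable,False
9,extraverted,1,7,False,open,False
10,critical,1,7,True,agreeable,False
11,dependable,1,7,False,dependable,False
12,anxious,1,7,True,open,False
13,open,1,7,False,open,False
14,reserved,1,7,True,open,False
15,sympathetic,1,7,False,agreeable,False
16,careless,1,7,True,dependable,False
17,calm,1,7,False,open,False
18,conventional,1,7,True,open,False
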