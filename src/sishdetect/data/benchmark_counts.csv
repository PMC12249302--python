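table,image_id,reference_count,tp,fp,fn,recall,precision,f1
visual,169284650,146,143,3,3,97.9,97.9,97.9
visual,169282562,118,117,1,0,100.0,99.2,99.6
visual,169284039,77,67,4,5,93.1,94.4,93.7
visual,169285655,207,202,5,3,98.5,97.6,98.1
visual,168138203,62,61,0,1,98.4,100.0,99.2
visual,168138509,153,148,4,5,96.7,97.4,97.0
visual,169262486,43,42,0,1,97.7,100.0,98.8
visual,168138726,66,65,1,0,100.0,98.5,99.2
visual,169283283,86,84,0,2,97.7,100.0,98.8
visual,169284222,126,125,2,1,99.2,98.4,98.8
visual,168138775,168,164,4,0,100.0,97.6,98.8
visual,169262529,24,21,3,0,100.0,87.5,93.3
visual,168138327,59,55,4,0,100.0,93.2,96.5
visual,169282117,62,59,2,0,100.0,96.7,98.3
visual,169284146,28,31,0,3,91.2,100.0,95.4
visual,169285625,203,201,4,3,98.5,98.0,98.3
visual,169282871,62,61,1,0,100.0,98.4,99.2
visual,169283207,157,156,1,0,100.0,99.4,99.7
visual,169283699,167,161,7,2,98.8,95.8,97.3
visual,169284611,297,300,0,3,99.0,100.0,99.5
expert,169284650,27,27,0,0,100.0,100.0,100.0
expert,169282562,13,13,0,0,100.0,100.0,100.0
expert,169284039,21,20,0,1,95.2,100.0,97.6
expert,169285655,64,62,2,2,96.9,96.9,96.9
expert,168138203,21,20,0,1,95.2,100.0,97.6
expert,168138509,53,49,4,1,98.0,92.5,95.1
expert,169262486,3,3,0,0,100.0,100.0,100.0
expert,168138726,18,16,2,0,100.0,88.9,94.1
expert,169283283,9,8,1,0,100.0,88.9,94.1
expert,169284222,44,43,1,0,100.0,97.7,98.9
expert,168138775,41,41,0,0,100.0,100.0,100.0
expert,169262529,4,4,0,0,100.0,100.0,100.0
expert,168138327,14,14,0,0,100.0,100.0,100.0
expert,169282117,8,6,2,0,100.0,75.0,85.7
expert,169284146,11,11,0,0,100.0,100.0,100.0
expert,169285625,66,65,1,0,100.0,98.5,99.2
expert,169282871,10,10,0,0,100.0,100.0,100.0
expert,169283207,22,22,0,0,100.0,100.0,100.0
expert,169283699,8,7,1,0,100.0,87.5,93.3
expert,169284611,40,40,0,2,95.2,100.0,97.6
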