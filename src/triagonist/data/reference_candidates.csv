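sequence,GCGR_activity,GLP1R_activity,GIPR_activity,highest_similarity,mol_weight,isoelectric,instability_index,gravy,estimated_logP,estimated_PSA
YAEGTFFTSDYSKLHKEAAEAFINWLIQTKITD,0.5941,0.6354,0.51907,54.5,3839.22,5.01129,20.6667,-0.3333,-0.3333,850
YAEGTFSDDDWTGIDSRRASTPVNWLLGGSAPPSK,0.59582,0.63758,0.51879,53.8,3754.98,4.36003,61.9057,-0.7143,-0.7143,850
YAEGTFQFCDCKLCERENIRDFIQWLIQNHGTD,0.59285,0.6331,0.51893,45.5,3994.4,4.69742,28.0727,-0.6121,-0.6121,850
YAEGTFSDDDWTGIKMYNLWQRT [K (eK-eK-yE-C20DA)]YVIFQ,0.59932,0.64272,0.5185,34.5,3576.94,4.68447,32.7552,-0.6862,-0.6862,700
HGEGTFSDDDWTGIKMYNLWQRT [K (eK-eK-yE-C20DA)]YVIFGSAPPSK,0.59919,0.64196,0.51818,37.1,4033.44,6.75483,33.48,-0.7943,-0.7943,850
HGEGTFTDDDWTGIKMYNLWQRT [K (eK-eK-yE-C20DA)]YVIFQ,0.5991,0.6421,0.5183,37.9,3550.91,5.4294,18.4138,-0.8241,-0.8241,750
YSEGTAFTSDYSQMEHESAADFVNELIQIHGTI,0.59367,0.63479,0.51908,48.5,3691.89,4.07208,15.5152,-0.3697,-0.3697,900
HGEGTFSDDDWTGIKMYNLWQRT [K (eK-eK-yE-C20DA)]YVIFQ,0.59959,0.64288,0.51834,41.4,3536.88,5.4294,18.4138,-0.8276,-0.8276,750
YAEGTFQFDDWTGIKMRDNVNWLLWVPDGGSGAPP,0.59533,0.6369,0.5186,46.3,3941.3,4.05003,34.8971,-0.5086,-0.5086,650
YSEGTAFDDDWTGIKMYNLWQRT [K (eK-eK-yE-C20DA)]YVIFQ,0.59874,0.64213,0.51835,30.0,3576.94,4.68447,31.231,-0.6862,-0.6862,700
YSEGTAFTSDYKLCERECARDFINWLIQIHGTD,0.59468,0.63679,0.51874,57.6,3883.24,4.69742,20.0394,-0.5091,-0.5091,850
YAEGTFISDDWTGIKMYNLWQRT [K (eK-eK-yE-C20DA)]YVIFQ,0.59882,0.64252,0.5187,40.0,3575.01,6.11897,32.7552,-0.4103,-0.4103,650
HGEGTFSDDDDKYLSASASDFFINWLIQTKITD,0.59247,0.63218,0.51911,60.6,3737.94,4.15507,-1.397,-0.5364,-0.5364,950
YLNGTFFVSDPSKLHSEQAEAAVQYLGYSKAPG,0.59509,0.63791,0.51859,45.5,3575.89,5.44531,22.2242,-0.3515,-0.3515,700
YAEGTFSDDDWTGIKMYNLRDVVQWLVAGGPGAPP,0.59467,0.63662,0.5189,53.8,3827.19,4.05003,43.2229,-0.3286,-0.3286,600
HGEGTAFTSDYSKLHKEAAHEFVNWLFYGGSGAPP,0.59601,0.63832,0.51886,64.1,3809.07,5.76946,23.6431,-0.5714,-0.5714,750
YAEGTFSDDDWTGIKMYNLWFIANWLIQTKITD,0.59495,0.63654,0.51917,54.5,3957.38,4.19656,28.0212,-0.2667,-0.2667,750
YAEGTFSDDDWTGIKMYNLWFVVQWLVAGGPGAPP,0.59485,0.63749,0.51924,56.4,3889.3,4.05003,44.4857,-0.0457,-0.0457,500
HHLYDDQFDDWKLCERECARDFINWLIQIHGTD,0.59197,0.63246,0.51834,42.4,4133.5,4.72022,25.4061,-0.8455,-0.8455,900
YAGGTFSYDDWTGIKMYNLWQEI [K (eK-eK-yE-C20DA)]YKPDGFSGAPP,0.60014,0.64351,0.5183,35.9,4004.39,4.68447,51.9971,-0.7314,-0.7314,650
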