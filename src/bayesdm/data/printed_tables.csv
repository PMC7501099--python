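analysis,task,target,row,mean,lower,upper,probability,direction
group_diff,delay,SUD,posterior,0.30,0.06,0.54,99,greater
group_diff,delay,SUD,prior,0.37,0.10,0.64,,greater
group_diff,delay,SUD,likelihood,0.24,-0.02,0.51,,greater
group_diff,delay,ND,posterior,0.21,0.03,0.40,99,greater
group_diff,delay,ND,prior,0.37,0.10,0.64,,greater
group_diff,delay,ND,likelihood,0.08,-0.16,0.34,,greater
group_diff,prob_gain,SUD,posterior,-0.13,-0.38,0.12,84,less
group_diff,prob_gain,SUD,prior,-0.16,-0.44,0.13,,less
group_diff,prob_gain,SUD,likelihood,-0.09,-0.37,0.19,,less
group_diff,prob_gain,ND,posterior,-0.11,-0.30,0.08,88,less
group_diff,prob_gain,ND,prior,-0.16,-0.44,0.13,,less
group_diff,prob_gain,ND,likelihood,-0.06,-0.33,0.21,,less
group_diff,prob_loss,SUD,posterior,-0.26,-0.49,-0.02,98,less
group_diff,prob_loss,SUD,prior,-0.16,-0.44,0.13,,less
group_diff,prob_loss,SUD,likelihood,-0.27,-0.54,-0.01,,less
group_diff,prob_loss,ND,posterior,-0.19,-0.38,-0.01,98,less
group_diff,prob_loss,ND,prior,-0.16,-0.44,0.13,,less
group_diff,prob_loss,ND,likelihood,-0.21,-0.48,0.04,,less
group_diff,loss_aversion,SUD,posterior,-0.05,-0.29,0.19,65,less
group_diff,loss_aversion,SUD,prior,-0.44,-0.71,-0.17,,less
group_diff,loss_aversion,SUD,likelihood,0.09,-0.18,0.36,,less
group_diff,loss_aversion,ND,posterior,-0.14,-0.33,0.04,93,less
group_diff,loss_aversion,ND,prior,-0.44,-0.71,-0.17,,less
group_diff,loss_aversion,ND,likelihood,0.12,-0.14,0.37,,less
prediction,delay,sud_criteria,posterior,0.12,0.03,0.20,99,greater
prediction,delay,sud_criteria,prior,0.25,0.00,0.50,,greater
prediction,delay,sud_criteria,likelihood,0.10,0.01,0.20,,greater
prediction,delay,nd_criteria,posterior,0.03,-0.06,0.11,72,greater
prediction,delay,nd_criteria,prior,0.25,0.00,0.50,,greater
prediction,delay,nd_criteria,likelihood,0.00,-0.10,0.09,,greater
prediction,delay,sud_qfi,posterior,0.04,-0.05,0.15,83,greater
prediction,delay,sud_qfi,prior,0.25,0.00,0.50,,greater
prediction,delay,sud_qfi,likelihood,0.11,0.00,0.22,,greater
prediction,delay,nd_qfi,posterior,0.07,-0.03,0.14,93,greater
prediction,delay,nd_qfi,prior,0.25,0.00,0.50,,greater
prediction,delay,nd_qfi,likelihood,0.05,-0.04,0.15,,greater
prediction,prob_gain,sud_criteria,posterior,-0.04,-0.13,0.04,84,less
prediction,prob_gain,sud_criteria,prior,-0.25,-0.50,0.00,,less
prediction,prob_gain,sud_criteria,likelihood,-0.02,-0.11,0.08,,less
prediction,prob_gain,nd_criteria,posterior,-0.06,-0.14,0.03,90,less
prediction,prob_gain,nd_criteria,prior,-0.25,-0.50,0.00,,less
prediction,prob_gain,nd_criteria,likelihood,-0.03,-0.12,0.06,,less
prediction,prob_gain,sud_qfi,posterior,0.02,-0.09,0.12,40,less
prediction,prob_gain,sud_qfi,prior,-0.25,-0.50,0.00,,less
prediction,prob_gain,sud_qfi,likelihood,0.00,-0.10,0.10,,less
prediction,prob_gain,nd_qfi,posterior,0.03,-0.08,0.13,29,less
prediction,prob_gain,nd_qfi,prior,-0.25,-0.50,0.00,,less
prediction,prob_gain,nd_qfi,likelihood,0.03,-0.06,0.12,,less
prediction,prob_loss,sud_criteria,posterior,0.02,-0.07,0.10,34,less
prediction,prob_loss,sud_criteria,prior,-0.25,-0.50,0.00,,less
prediction,prob_loss,sud_criteria,likelihood,0.05,-0.04,0.14,,less
prediction,prob_loss,nd_criteria,posterior,-0.09,-0.17,-0.01,98,less
prediction,prob_loss,nd_criteria,prior,-0.25,-0.50,0.00,,less
prediction,prob_loss,nd_criteria,likelihood,-0.06,-0.16,0.03,,less
prediction,prob_loss,sud_qfi,posterior,0.03,-0.07,0.14,26,less
prediction,prob_loss,sud_qfi,prior,-0.25,-0.50,0.00,,less
prediction,prob_loss,sud_qfi,likelihood,0.02,-0.08,0.13,,less
prediction,prob_loss,nd_qfi,posterior,0.03,-0.07,0.13,31,less
prediction,prob_loss,nd_qfi,prior,-0.25,-0.50,0.00,,less
prediction,prob_loss,nd_qfi,likelihood,0.02,-0.08,0.11,,less
prediction,loss_aversion,sud_criteria,posterior,-0.14,-0.23,-0.06,99,less
prediction,loss_aversion,sud_criteria,prior,-0.25,-0.50,0.00,,less
prediction,loss_aversion,sud_criteria,likelihood,-0.13,-0.23,-0.03,,less
prediction,loss_aversion,nd_criteria,posterior,-0.10,-0.18,-0.01,98,less
prediction,loss_aversion,nd_criteria,prior,-0.25,-0.50,0.00,,less
prediction,loss_aversion,nd_criteria,likelihood,-0.07,-0.17,0.03,,less
prediction,loss_aversion,sud_qfi,posterior,-0.02,-0.13,0.09,62,less
prediction,loss_aversion,sud_qfi,prior,-0.25,-0.50,0.00,,less
prediction,loss_aversion,sud_qfi,likelihood,-0.04,-0.16,0.07,,less
prediction,loss_aversion,nd_qfi,posterior,-0.02,-0.10,0.09,57,less
prediction,loss_aversion,nd_qfi,prior,-0.25,-0.50,0.00,,less
prediction,loss_aversion,nd_qfi,likelihood,-0.02,-0.11,0.08,,less
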